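import numpy as np
import pytest

from mosaicmap import breed_sim as bs
from mosaicmap import synthetic_data as sd
from mosaicmap.variant_io import MISSING

from conftest import hw_sample, tiny_matrix


def wc_fst_oracle(calls_a, calls_b):
    """Scalar transcription of the 1984 two-population variance components.

    Independent of the vectorised implementation: per site, loops over the
    textbook formulas for a (among populations), b (among individuals
    within populations) and c (within individuals), then forms the
    ratio-of-sums mean.
    """
    num = den = 0.0
    per_site = []
    r = 2
    for row_a, row_b in zip(calls_a, calls_b):
        ga = [g for g in row_a if g != MISSING]
        gb = [g for g in row_b if g != MISSING]
        if len(ga) < 2 or len(gb) < 2:
            per_site.append(np.nan)
            continue
        n1, n2 = len(ga), len(gb)
        p1, p2 = sum(ga) / (2 * n1), sum(gb) / (2 * n2)
        h1, h2 = sum(g == 1 for g in ga) / n1, sum(g == 1 for g in gb) / n2
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        if a + b + c == 0:
            per_site.append(np.nan)
            continue
        per_site.append(a / (a + b + c))
        num += a
        den += a + b + c
    return np.array(per_site), (num / den if den else np.nan)


class TestWeirCockerhamFst:
    def test_matches_textbook_oracle_on_toy_matrices(self):
        """Vectorised estimator equals the scalar variance-components
        oracle to 1e-12, including missing data and skipped sites."""
        rng = np.random.default_rng(41)
        for trial in range(5):
            calls_a = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
            calls_b = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
            calls_a[rng.random(calls_a.shape) < 0.15] = MISSING
            calls_b[rng.random(calls_b.shape) < 0.15] = MISSING
            a = tiny_matrix(calls_a)
            b = tiny_matrix(calls_b)
            per_site, mean = bs.weir_cockerham_fst(a, b)
            o_site, o_mean = wc_fst_oracle(calls_a, calls_b)
            np.testing.assert_allclose(per_site, o_site, atol=1e-12, equal_nan=True)
            assert mean == pytest.approx(o_mean, abs=1e-12)

    def test_identical_large_samples_near_zero(self):
        model = sd.FounderModel(n_sites=5000, divergence_fst=0.0, seed=2)
        tau, _ = sd.draw_founder_frequencies(model)
        a = hw_sample(tau, 150, seed=3, prefix="x")
        b = hw_sample(tau, 150, seed=4, prefix="y")
        _, fst = bs.weir_cockerham_fst(a, b)
        assert fst == pytest.approx(0.0, abs=0.01)

    def test_fixed_difference_is_one(self):
        a = tiny_matrix(np.zeros((1, 100), dtype=np.int8))
        b = tiny_matrix(np.full((1, 100), 2, dtype=np.int8))
        per_site, mean = bs.weir_cockerham_fst(a, b)
        assert per_site[0] == pytest.approx(1.0, abs=1e-9)

    def test_balding_nichols_recovery(self):
        """Estimator recovers the Balding-Nichols divergence parameter."""
        model = sd.FounderModel(n_sites=10_000, divergence_fst=0.15, seed=6)
        tau, ind = sd.draw_founder_frequencies(model)
        a = hw_sample(tau, 200, seed=7, prefix="t")
        b = hw_sample(ind, 200, seed=8, prefix="i")
        _, fst = bs.weir_cockerham_fst(a, b)
        assert fst == pytest.approx(0.15, abs=0.03)


def _small_params(**kw):
    base = dict(
        ancestral_n=200,
        burnin_gens=50,
        divergence_gens=200,
        admixture_gens=5,
        n_brahman_out=200,
        n_loci=4,
        locus_length=1_000_000,
        mutation_rate=0.0,
        init_sites_per_locus=600,
        sample_size=80,
        seed=1,
    )
    base.update(kw)
    return bs.SimParams(**base)


class TestBreedFormation:
    def test_no_divergence_gives_near_zero_fst(self):
        p = _small_params(divergence_gens=0)
        m, _ = bs.mean_fst_over_replicates(p, 3, pops="founders")
        assert m == pytest.approx(0.0, abs=0.02)

    def test_drift_fst_matches_closed_form(self):
        """At t/2N = 0.5 without mutation, founder FST ~ 1 - e^(-t/2N)."""
        p = _small_params(ancestral_n=200, divergence_gens=200)  # t/2N = 0.5
        m, _ = bs.mean_fst_over_replicates(p, 10, pops="founders")
        assert m == pytest.approx(1 - np.exp(-0.5), abs=0.05)

    def test_backcross_pedigree_expectation(self):
        """F1 followed by 4 backcrosses to indicine leaves ~2^-5 taurine."""
        fracs = [
            bs.simulate_breed_formation(
                _small_params(
                    admixture_mode="grading_up", admixture_gens=4,
                    n_backcross_gens=4, seed=s,
                )
            ).realized_taurine_fraction
            for s in (1, 2, 3, 4)
        ]
        assert np.mean(fracs) == pytest.approx(2**-5, abs=0.015)

    def test_crossbreed_mode_is_half_taurine(self):
        out = bs.simulate_breed_formation(_small_params(seed=9))
        assert out.realized_taurine_fraction == pytest.approx(0.5, abs=0.06)

    def test_ancestry_tracts_tile_genome(self):
        out = bs.simulate_breed_formation(_small_params(seed=5))
        p = _small_params()
        for haps in out.tracts.tracts.values():
            for hap in haps:
                assert sum(e - s + 1 for s, e, _ in hap) == p.genome_length

    def test_seed_determinism(self):
        a = bs.simulate_breed_formation(_small_params(seed=12))
        b = bs.simulate_breed_formation(_small_params(seed=12))
        np.testing.assert_array_equal(a.brahman.calls, b.brahman.calls)
        assert a.tracts.tracts == b.tracts.tracts

    def test_neutrality_mean_frequency_is_martingale(self):
        """Total allele-frequency mass (absorbed sites counted at their
        absorbing value: 1 when fixed, 0 when lost) is conserved in
        expectation across replicate drift runs."""
        rng = np.random.default_rng(51)
        p = _small_params(init_sites_per_locus=1500)
        deltas = []
        n0 = None
        for _ in range(20):
            phase = bs._FreqPhase(p, np.random.default_rng(int(rng.integers(2**31))))
            mass0 = phase.counts[0].sum() / phase.two_n
            n0 = len(phase.counts[0])
            phase.run(30)
            mass1 = phase.counts[0].sum() / phase.two_n + phase.fixed_removed
            deltas.append(mass1 - mass0)
        assert abs(np.mean(deltas)) / n0 < 0.01

    def test_rescaling_invariance(self):
        """Scaled and unscaled runs with matched t/2N agree on mean FST."""
        unscaled = _small_params(ancestral_n=400, divergence_gens=200, burnin_gens=0)
        scaled = _small_params(
            ancestral_n=400, divergence_gens=200, burnin_gens=0, scale_factor=4.0
        )
        m_u, _ = bs.mean_fst_over_replicates(unscaled, 6, pops="founders")
        m_s, _ = bs.mean_fst_over_replicates(scaled, 6, pops="founders")
        assert m_u == pytest.approx(m_s, abs=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bs.SimParams(scale_factor=0.5)
        with pytest.raises(ValueError):
            bs.SimParams(ancestral_n=1)
        with pytest.raises(ValueError):
            bs.SimParams(admixture_mode="magic")


class TestTuneDivergence:
    def test_zero_target_needs_no_divergence(self):
        t, f = bs.tune_divergence(0.0, _small_params())
        assert t == 0 and f == 0.0

    def test_bisection_reaches_target_band(self):
        p = _small_params(ancestral_n=100, divergence_gens=60, n_brahman_out=60,
                          admixture_gens=2, sample_size=50, init_sites_per_locus=400)
        t, f = bs.tune_divergence(0.2, p, tolerance=0.04, n_replicates=2, pops="founders")
        assert f == pytest.approx(0.2, abs=0.06)
        # drift-only closed form brackets the tuned time
        implied = -2 * p.scaled_n * np.log(1 - f)
        assert 0.3 * implied < t < 3 * implied

    def test_monotone_in_divergence_time(self):
        p = _small_params(ancestral_n=100, n_brahman_out=60, admixture_gens=2,
                          sample_size=50, init_sites_per_locus=400)
        means = [
            bs.mean_fst_over_replicates(
                bs.SimParams(**{**p.__dict__, "divergence_gens": t}), 6, pops="founders"
            )[0]
            for t in (10, 60, 200)
        ]
        assert means[0] < means[1] < means[2]
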