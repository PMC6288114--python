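import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mosaicmap import ancestry
from mosaicmap.ancestry import (
    animal_composition,
    bosind_snp,
    bosind_values,
    cohort_window_means,
    compute_window_stats,
    heatmap_matrix,
    percent_difference,
    select_top_windows,
    window_average,
    window_percent_difference,
)


class TestBosindSnp:
    @pytest.mark.parametrize(
        "p_ref,p_ind,expected",
        [
            (0.5, 0.5, 0.0),          # individual looks like the reference
            (1.0, 0.0, 1.0),          # fixed difference: Hs=0, Ht=0.5
            (0.2, 1.0, 0.32 / 0.48),  # hand evaluation of the Hs/Ht forms
            (0.0, 0.5, 1.0 / 3.0),
        ],
    )
    def test_hand_evaluated_values(self, p_ref, p_ind, expected):
        assert bosind_snp(p_ref, p_ind) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_monomorphic_agreement_undefined(self, p):
        assert np.isnan(bosind_snp(p, p))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bosind_snp(1.2, 0.5)
        with pytest.raises(ValueError):
            bosind_snp(0.5, 0.3)

    @given(
        p_ref=st.floats(0, 1, allow_nan=False),
        p_ind=st.sampled_from([0.0, 0.5, 1.0]),
    )
    @settings(max_examples=300, derandomize=True)
    def test_closed_form_symmetry_and_bounds(self, p_ref, p_ind):
        """(Ht-Hs)/Ht equals (p1-p2)^2/(2 Ht), is symmetric and >= 0."""
        v = bosind_values(np.array([p_ref]), np.array([p_ind]))[0]
        pbar = (p_ref + p_ind) / 2
        ht = 2 * pbar * (1 - pbar)
        if ht == 0:
            assert np.isnan(v)
        else:
            # rel tolerance absorbs cancellation when p_ref ~ p_ind ~ 0 or 1
            assert v == pytest.approx((p_ref - p_ind) ** 2 / (2 * ht), rel=1e-6, abs=1e-9)
            assert v >= -1e-15
            swapped = bosind_values(np.array([p_ind]), np.array([p_ref]))[0]
            assert v == pytest.approx(swapped, abs=1e-12)


class TestWindowAverage:
    def test_two_value_window(self):
        out = window_average([0.1, 0.3], [10, 20], window=250_000, min_snps=2)
        assert len(out) == 1
        assert out["bosind_avg"].iloc[0] == pytest.approx(0.2)
        assert bool(out["callable"].iloc[0])

    def test_all_undefined_window_is_no_call(self):
        out = window_average([np.nan, np.nan, 0.5], [10, 20, 300_000], 250_000, min_snps=1)
        assert out["win_index"].tolist() == [1]  # window 0 vanishes entirely

    def test_matches_bin_then_mean_oracle(self):
        rng = np.random.default_rng(13)
        pos = np.sort(rng.integers(1, 1_000_001, size=1000))
        vals = rng.random(1000)
        vals[rng.random(1000) < 0.1] = np.nan
        out = window_average(vals, pos, window=250_000, min_snps=1)
        for w in range(4):
            sel = ((pos - 1) // 250_000 == w) & ~np.isnan(vals)
            expected = vals[sel][~np.isnan(vals[sel])].mean()
            got = out.loc[out["win_index"] == w, "bosind_avg"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            window_average([0.1, 0.2], [500, 100])


class TestPercentDifference:
    def test_reported_indicine_region_example(self):
        """A window scoring 0.67 vs taurine and 0.11 vs indicine gives a
        strongly negative (indicine-like) percent difference."""
        assert percent_difference(0.67, 0.11) == pytest.approx(-143.59, abs=0.01)

    def test_equal_sides_zero(self):
        assert percent_difference(0.25, 0.25) == 0.0

    def test_symmetric_form(self):
        assert percent_difference(0.1, 0.3) == pytest.approx(100.0)

    def test_both_zero_undefined(self):
        assert np.isnan(percent_difference(0.0, 0.0))


def _stats_from_frame(df, window=250_000, min_snps=1):
    df = df.copy()
    df["start"] = df["win_index"] * window + 1
    df["end"] = (df["win_index"] + 1) * window
    for c in ("n_snp_tau", "n_snp_ind"):
        if c not in df:
            df[c] = 50
    df["callable_tau"] = ~df["bosind_tau"].isna()
    df["callable_ind"] = ~df["bosind_ind"].isna()
    glob = pd.DataFrame(
        {
            "animal": sorted(df["animal"].unique()),
            "gsum_tau": 1.0, "gn_tau": 10, "gsum_ind": 1.0, "gn_ind": 10,
            "global_tau": 0.1, "global_ind": 0.1,
        }
    )
    return ancestry.WindowStatTable(window, min_snps, df, glob)


class TestTopWindows:
    def _random_pct(self, n=100, seed=17):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "chrom": "1",
                "win_index": np.arange(n),
                "pct_diff": rng.normal(size=n),
            }
        )

    def test_five_percent_of_hundred_is_five(self):
        top = select_top_windows(self._random_pct(), "taurine", 0.05)
        assert len(top) == 5

    def test_input_order_invariance(self):
        pct = self._random_pct()
        shuffled = pct.sample(frac=1, random_state=1)
        a = select_top_windows(pct, "indicine", 0.05)
        b = select_top_windows(shuffled, "indicine", 0.05)
        pd.testing.assert_frame_equal(a, b)

    def test_directions_pick_opposite_tails(self):
        pct = self._random_pct()
        tau = select_top_windows(pct, "taurine", 0.05)
        ind = select_top_windows(pct, "indicine", 0.05)
        assert tau["pct_diff"].min() > ind["pct_diff"].max()


class TestComposition:
    def test_all_taurine_lower_gives_fraction_one(self):
        df = pd.DataFrame(
            {
                "animal": "a0",
                "chrom": "1",
                "win_index": range(10),
                "bosind_tau": 0.1,
                "bosind_ind": 0.4,
            }
        )
        comp = animal_composition(_stats_from_frame(df))
        assert comp["taurine_window_fraction"].iloc[0] == 1.0

    def test_symmetric_references_split_evenly(self, mosaic_cohort):
        """Running against the same reference twice ties every window;
        deterministic tie-breaking lands near 50/50."""
        g, _, (tau, _) = mosaic_cohort
        stats = compute_window_stats(g, tau, tau)
        comp = animal_composition(stats)
        assert comp["taurine_window_fraction"].mean() == pytest.approx(0.5, abs=0.06)


class TestHeatmap:
    def _stats(self):
        df = pd.DataFrame(
            {
                "animal": ["young", "young", "young", "old", "old", "old"],
                "chrom": "1",
                "win_index": [0, 1, 2, 0, 1, 2],
                "bosind_tau": [0.1, 0.2, 0.3, 0.3, 0.2, 0.1],
                "bosind_ind": [0.3, 0.2, 0.1, 0.1, 0.2, 0.3],
            }
        )
        return _stats_from_frame(df)

    def test_matrix_shape_and_year_order(self):
        mat = heatmap_matrix(self._stats(), "1", {"old": 1953, "young": 2005})
        assert mat.shape == (2, 3)
        assert list(mat.index) == ["old", "young"]

    def test_missing_year_placed_last(self, caplog):
        with caplog.at_level("INFO"):
            mat = heatmap_matrix(self._stats(), "1", {"young": 2005})
        assert list(mat.index) == ["young", "old"]
        assert "without birth year" in caplog.text

    def test_render_writes_figure(self, tmp_path):
        from mosaicmap.ancestry import render_heatmap

        mat = heatmap_matrix(self._stats(), "1", {})
        out = tmp_path / "heatmap.pdf"
        render_heatmap(mat, out, title="chr1")
        assert out.stat().st_size > 0

    def test_cells_equal_recomputed_percent_difference(self):
        stats = self._stats()
        mat = heatmap_matrix(stats, "1", {})
        pct = window_percent_difference(stats)
        for _, row in pct.iterrows():
            assert mat.loc[row["animal"], row["win_index"]] == pytest.approx(
                row["pct_diff"], nan_ok=True
            )


class TestMosaicRecovery:
    def test_composition_recovers_truth_fraction(self, mosaic_cohort):
        """Window-fraction composition of a 10% taurine mosaic at F=0.25
        recovers the realized tract fraction within 0.05."""
        g, truth, (tau, ind) = mosaic_cohort
        stats = compute_window_stats(g, tau, ind)
        comp = animal_composition(stats)
        realized = truth.realized_taurine_fraction()
        assert comp["taurine_window_fraction"].mean() == pytest.approx(realized, abs=0.05)
        # per-SNP global differentiation is lower against the majority origin
        assert (comp["global_ind"] < comp["global_tau"]).all()

    def test_planted_indicine_region_dominates_selection(self, founders_f25):
        """A region made purely indicine in every animal is what the
        indicine-direction top-window selection returns."""
        import mosaicmap.synthetic_data as sd

        tau, ind = founders_f25
        spec = sd.MosaicSpec(10_000_000, 0.3, 1_000_000, 20, seed=77)
        g, _ = sd.simulate_mosaic_cohort(spec, (tau, ind))
        rng = np.random.default_rng(78)
        planted = set(range(10, 15))  # windows 10-14 forced indicine-fixed
        pos = g.sites["pos"].to_numpy()
        in_region = np.isin((pos - 1) // 250_000, list(planted))
        g.calls[in_region] = rng.binomial(
            2, ind.af[in_region][:, None], size=(in_region.sum(), g.n_animals)
        ).astype(np.int8)
        stats = compute_window_stats(g, tau, ind)
        top = select_top_windows(cohort_window_means(stats), "indicine", 5 / 40)
        assert len(set(top["win_index"]) & planted) >= 4
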