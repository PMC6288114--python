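"""Forward Wright–Fisher simulation of breed formation, and the
Weir & Cockerham FST estimator.

The demographic model is the one used as the neutral null for the mosaic
genome: a single ancestral population evolves to mutation–drift
equilibrium, splits into a taurine and an indicine population that
diverge in isolation, and an admixed (Brahman-like) population is then
formed from the two and random-mates for a fixed number of generations.
No selection acts anywhere.

Two admixture designs are provided: a literal cross-breeding event (an
F1 hybrid population that then random-mates) and a grading-up design in
which the hybrid line is repeatedly backcrossed to indicine sires before
random mating — the latter reproduces the mostly-indicine makeup of the
real breed. Ancestry of every chromosome tract is tracked through
meiosis, so the simulated cohort comes with ground-truth tracts.

Genomes are ``n_loci`` independent loci (free recombination between
loci); within a locus at most one crossover occurs per meiosis, at the
stated low per-locus rate. Mutation is infinite-sites within loci.

Desk-scale runs rescale the model: population size and generation counts
shrink by ``scale_factor`` while per-generation rates grow by the same
factor, preserving the drift time t/2N and the population-scaled
mutation/recombination rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic_data import AncestryTractSet, INDICINE, TAURINE, Tract
from .variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Demographic and genomic parameters of the breed-formation model.

    Defaults are the full-scale model: ancestral diploid size 10,000,
    100,000 generations of burn-in, 10,000 generations of divergence,
    30 generations of admixture producing 1,000 admixed animals, and
    mutation/recombination rates of 0.01 per 10 Mb locus per generation.
    Set ``scale_factor`` ~ 20 for desk-scale runs.
    """

    ancestral_n: int = 10_000
    burnin_gens: int = 100_000
    divergence_gens: int = 10_000
    admixture_gens: int = 30
    n_brahman_out: int = 1_000
    n_loci: int = 5
    locus_length: int = 10_000_000
    mutation_rate: float = 0.01
    recombination_rate: float = 0.01
    scale_factor: float = 1.0
    admixture_mode: str = "crossbreed"  # or "grading_up"
    n_backcross_gens: int = 2
    init_sites_per_locus: int | None = None
    sample_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.ancestral_n < 2 or self.n_brahman_out < 2:
            raise ValueError("population sizes must be >= 2")
        if self.admixture_mode not in ("crossbreed", "grading_up"):
            raise ValueError("admixture_mode must be 'crossbreed' or 'grading_up'")
        if min(self.burnin_gens, self.divergence_gens, self.admixture_gens) < 0:
            raise ValueError("generation counts must be non-negative")
        s = self.scale_factor
        if self.divergence_gens > 0:
            t2n = self.divergence_gens / (2 * self.ancestral_n)
            t2n_s = self.scaled_divergence_gens / (2 * self.scaled_n)
            if abs(t2n_s - t2n) > 0.01 * max(t2n, 1e-12):
                raise ValueError(
                    "rescaling distorts t/2N by more than 1%; adjust scale_factor"
                )

    # -- rescaled quantities -------------------------------------------------
    @property
    def scaled_n(self) -> int:
        return max(2, round(self.ancestral_n / self.scale_factor))

    @property
    def scaled_burnin_gens(self) -> int:
        return round(self.burnin_gens / self.scale_factor)

    @property
    def scaled_divergence_gens(self) -> int:
        return round(self.divergence_gens / self.scale_factor)

    @property
    def scaled_mu(self) -> float:
        return self.mutation_rate * self.scale_factor

    @property
    def scaled_r(self) -> float:
        return min(1.0, self.recombination_rate * self.scale_factor)

    @property
    def genome_length(self) -> int:
        return self.n_loci * self.locus_length


@dataclass
class SimOutput:
    """Sampled genotype matrices plus ground-truth ancestry of the admixed
    haplotypes (coordinates concatenate loci into one genome axis)."""

    taurine: GenotypeMatrix
    indicine: GenotypeMatrix
    brahman: GenotypeMatrix
    tracts: AncestryTractSet
    realized_taurine_fraction: float
    n_segregating: int


# ---------------------------------------------------------------------------
# Frequency-resolution phases (burn-in, divergence)
# ---------------------------------------------------------------------------

def _equilibrium_sfs_counts(
    rng: np.random.Generator, n_sites: int, two_n: int
) -> np.ndarray:
    """Draw standing-variation allele counts from the neutral 1/x SFS."""
    j = np.arange(1, two_n)
    w = 1.0 / j
    return rng.choice(j, size=n_sites, p=w / w.sum())


class _FreqPhase:
    """Per-site allele-count evolution of one or two populations.

    Sites are rows of parallel arrays (locus, position, counts). New
    mutations enter as singletons; sites lost or fixed everywhere are
    pruned. This is an exact neutral Wright–Fisher model for unlinked
    site frequencies (within-locus linkage does not affect marginal
    frequency trajectories under neutrality).
    """

    def __init__(self, p: SimParams, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self.two_n = 2 * p.scaled_n
        self.locus = np.empty(0, dtype=np.int32)
        self.pos = np.empty(0, dtype=np.int64)
        self.counts = [np.empty(0, dtype=np.int64)]  # one array per population
        self.fixed_removed = 0  # sites pruned because fixed in every population
        if p.init_sites_per_locus:
            n0 = p.init_sites_per_locus * p.n_loci
            self.locus = rng.integers(0, p.n_loci, size=n0).astype(np.int32)
            self.pos = rng.integers(1, p.locus_length + 1, size=n0)
            self.counts = [_equilibrium_sfs_counts(rng, n0, self.two_n)]

    def _influx(self, pop: int) -> None:
        lam = self.two_n * self.p.scaled_mu * self.p.n_loci
        n_new = self.rng.poisson(lam)
        if n_new == 0:
            return
        self.locus = np.concatenate(
            [self.locus, self.rng.integers(0, self.p.n_loci, size=n_new).astype(np.int32)]
        )
        self.pos = np.concatenate(
            [self.pos, self.rng.integers(1, self.p.locus_length + 1, size=n_new)]
        )
        for k in range(len(self.counts)):
            add = np.ones(n_new, dtype=np.int64) if k == pop else np.zeros(n_new, dtype=np.int64)
            self.counts[k] = np.concatenate([self.counts[k], add])

    def _prune(self) -> None:
        lost = np.ones(len(self.locus), dtype=bool)
        fixed = np.ones(len(self.locus), dtype=bool)
        for c in self.counts:
            lost &= c == 0
            fixed &= c == self.two_n
        keep = ~(lost | fixed)
        self.fixed_removed += int(fixed.sum())
        if keep.all():
            return
        self.locus = self.locus[keep]
        self.pos = self.pos[keep]
        self.counts = [c[keep] for c in self.counts]

    def step(self) -> None:
        for k in range(len(self.counts)):
            c = self.counts[k]
            if len(c):
                self.counts[k] = self.rng.binomial(self.two_n, c / self.two_n)
            self._influx(k)
        self._prune()

    def split(self) -> None:
        """Duplicate the single population into two daughters."""
        assert len(self.counts) == 1
        self.counts = [self.counts[0].copy(), self.counts[0].copy()]

    def run(self, gens: int) -> None:
        for _ in range(gens):
            self.step()

    def frequencies(self) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
        """Sites sorted by (locus, pos), deduplicated, with per-pop freqs."""
        order = np.lexsort((self.pos, self.locus))
        locus, pos = self.locus[order], self.pos[order]
        freqs = [c[order] / self.two_n for c in self.counts]
        if len(locus):
            dup = np.zeros(len(locus), dtype=bool)
            dup[1:] = (locus[1:] == locus[:-1]) & (pos[1:] == pos[:-1])
            if dup.any():  # infinite-sites collision on the integer grid
                locus, pos = locus[~dup], pos[~dup]
                freqs = [f[~dup] for f in freqs]
        return locus, pos, freqs


# ---------------------------------------------------------------------------
# Individual-based admixture phase with tract tracking
# ---------------------------------------------------------------------------

def _slice_tracts(tracts: list[Tract], lo: int, hi: int) -> list[Tract]:
    out = []
    for start, end, origin in tracts:
        if end < lo or start > hi:
            continue
        out.append((max(start, lo), min(end, hi), origin))
    return out


def _merge_tracts(pieces: list[Tract]) -> list[Tract]:
    merged: list[Tract] = []
    for t in pieces:
        if merged and merged[-1][2] == t[2] and merged[-1][1] + 1 == t[0]:
            merged[-1] = (merged[-1][0], t[1], t[2])
        else:
            merged.append(t)
    return merged


#: per-haplotype tracts are stored per locus (global coordinates); locus
#: lists are treated as immutable and shared by reference when a meiosis
#: transmits a locus without crossover.
LocusTracts = list[list[Tract]]


class _AdmixedPopulation:
    """Diploid admixed population: allele matrix + per-haplotype tracts."""

    def __init__(
        self,
        p: SimParams,
        rng: np.random.Generator,
        site_locus: np.ndarray,
        site_pos: np.ndarray,
        freq_tau: np.ndarray,
        freq_ind: np.ndarray,
    ):
        self.p = p
        self.rng = rng
        self.site_locus = site_locus
        self.site_pos = site_pos
        # sites arrive sorted by (locus, pos): locus boundaries as slices
        self.locus_bounds = np.searchsorted(site_locus, np.arange(p.n_loci + 1))
        self.freq_tau = freq_tau
        self.freq_ind = freq_ind
        n = p.n_brahman_out
        # F1 founding: one taurine gamete, one indicine gamete per animal
        tau_h = (rng.random((n, len(site_pos))) < freq_tau).astype(np.int8)
        ind_h = (rng.random((n, len(site_pos))) < freq_ind).astype(np.int8)
        self.haps = np.empty((2 * n, len(site_pos)), dtype=np.int8)
        self.haps[0::2] = tau_h
        self.haps[1::2] = ind_h
        self.tracts: list[LocusTracts] = []
        for _ in range(n):
            self.tracts.append(self._pure_locus_tracts(TAURINE))
            self.tracts.append(self._pure_locus_tracts(INDICINE))

    def _pure_locus_tracts(self, origin: str) -> LocusTracts:
        LL = self.p.locus_length
        return [[(l * LL + 1, (l + 1) * LL, origin)] for l in range(self.p.n_loci)]

    def _founder_gametes(self, k: int, origin: str) -> tuple[np.ndarray, list[LocusTracts]]:
        freq = self.freq_tau if origin == TAURINE else self.freq_ind
        alleles = (self.rng.random((k, len(self.site_pos))) < freq).astype(np.int8)
        tr = [self._pure_locus_tracts(origin) for _ in range(k)]
        return alleles, tr

    def _meioses(self, parents: np.ndarray) -> tuple[np.ndarray, list[LocusTracts]]:
        """One gamete per entry of ``parents`` (animal indices)."""
        p, rng = self.p, self.rng
        G, L = len(parents), p.n_loci
        start_h = rng.integers(0, 2, size=(G, L), dtype=np.int8)
        co = rng.random((G, L)) < p.recombination_rate
        xpos = rng.integers(1, p.locus_length + 1, size=(G, L))
        gametes = np.empty((G, self.haps.shape[1]), dtype=np.int8)
        out_tracts: list[LocusTracts] = [[] for _ in range(G)]
        LL = p.locus_length
        for l in range(L):
            s0, s1 = self.locus_bounds[l], self.locus_bounds[l + 1]
            rows = 2 * parents + start_h[:, l]
            gametes[:, s0:s1] = self.haps[rows, s0:s1]
            # rare within-locus crossovers: overwrite the distal slice
            for g in np.nonzero(co[:, l])[0]:
                cut_local = int(xpos[g, l])
                cut_site = s0 + int(
                    np.searchsorted(self.site_pos[s0:s1], cut_local, side="right")
                )
                other = 2 * parents[g] + (1 - start_h[g, l])
                gametes[g, cut_site:s1] = self.haps[other, cut_site:s1]
        for g in range(G):
            par = self.tracts[2 * parents[g]], self.tracts[2 * parents[g] + 1]
            locus_tracts: LocusTracts = []
            for l in range(L):
                h0 = int(start_h[g, l])
                if not co[g, l]:
                    locus_tracts.append(par[h0][l])  # shared, never mutated
                else:
                    off = l * LL
                    cut = off + int(xpos[g, l])
                    pieces = _slice_tracts(par[h0][l], off + 1, cut)
                    pieces += _slice_tracts(par[1 - h0][l], cut + 1, off + LL)
                    locus_tracts.append(_merge_tracts(pieces))
            out_tracts[g] = locus_tracts
        return gametes, out_tracts

    def next_generation(self, backcross_to_indicine: bool) -> None:
        n = self.p.n_brahman_out
        dam_gam, dam_tr = self._meioses(self.rng.integers(0, n, size=n))
        if backcross_to_indicine:
            sire_gam, sire_tr = self._founder_gametes(n, INDICINE)
        else:
            sire_gam, sire_tr = self._meioses(self.rng.integers(0, n, size=n))
        haps = np.empty_like(self.haps[: 2 * n])
        haps[0::2] = dam_gam
        haps[1::2] = sire_gam
        self.haps = haps
        tracts: list[LocusTracts] = []
        for i in range(n):
            tracts.append(dam_tr[i])
            tracts.append(sire_tr[i])
        self.tracts = tracts

    def haplotype_tracts(self, hap_index: int) -> list[Tract]:
        """Flattened, merged tract list of one haplotype (whole genome)."""
        flat: list[Tract] = []
        for locus_list in self.tracts[hap_index]:
            flat.extend(locus_list)
        return _merge_tracts(flat)


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def _sites_frame(p: SimParams, site_locus: np.ndarray, site_pos: np.ndarray) -> pd.DataFrame:
    width = len(str(p.n_loci))
    chroms = np.array([f"sim{l + 1:0{width}d}" for l in range(p.n_loci)])
    return pd.DataFrame(
        {
            "chrom": chroms[site_locus],
            "pos": site_pos,
            "ref": "A",
            "alt": "C",
        }
    )


def _hw_sample(
    rng: np.random.Generator, freqs: np.ndarray, n: int, prefix: str,
    sites: pd.DataFrame,
) -> GenotypeMatrix:
    calls = rng.binomial(2, freqs[:, None], size=(len(freqs), n)).astype(np.int8)
    animals = [f"{prefix}_{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(sites.copy(), animals, calls)


def simulate_breed_formation(p: SimParams) -> SimOutput:
    """Run the full neutral breed-formation model and sample the output.

    Returns genotype samples from the taurine, indicine and admixed
    populations over all sites segregating at the end of the run, plus
    the ground-truth ancestry tracts of the sampled admixed animals.
    """
    rng = np.random.default_rng(p.seed)
    phase = _FreqPhase(p, rng)
    if p.mutation_rate == 0 and not p.init_sites_per_locus:
        logger.warning("no mutation and no standing variation: expect 0 segregating sites")
    phase.run(p.scaled_burnin_gens)
    phase.split()
    phase.run(p.scaled_divergence_gens)
    site_locus, site_pos, (freq_tau, freq_ind) = phase.frequencies()
    n_seg = len(site_pos)

    pop = _AdmixedPopulation(p, rng, site_locus, site_pos, freq_tau, freq_ind)
    n_bc = p.n_backcross_gens if p.admixture_mode == "grading_up" else 0
    for gen in range(p.admixture_gens):
        pop.next_generation(backcross_to_indicine=gen < n_bc)

    sites = _sites_frame(p, site_locus, site_pos)
    n_s = min(p.sample_size, p.n_brahman_out)
    pick = rng.choice(p.n_brahman_out, size=n_s, replace=False)
    calls = (pop.haps[2 * pick] + pop.haps[2 * pick + 1]).T.astype(np.int8)
    animals = [f"brahman_{i + 1:03d}" for i in range(n_s)]
    brahman = GenotypeMatrix(sites.copy(), animals, calls)
    tract_map = {
        a: (pop.haplotype_tracts(2 * k), pop.haplotype_tracts(2 * k + 1))
        for a, k in zip(animals, pick)
    }
    truth = AncestryTractSet("sim_genome", p.genome_length, tract_map)
    taurine = _hw_sample(rng, freq_tau, n_s, "taurine", sites)
    indicine = _hw_sample(rng, freq_ind, n_s, "indicine", sites)
    return SimOutput(
        taurine=taurine,
        indicine=indicine,
        brahman=brahman,
        tracts=truth,
        realized_taurine_fraction=truth.realized_taurine_fraction(),
        n_segregating=n_seg,
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) FST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[np.ndarray, float]:
    """Two-population Weir & Cockerham (1984) FST.

    Computes the variance components a (between populations),
    b (between individuals within populations) and c (within
    individuals) per site from genotype counts, with the standard
    sample-size corrections. Returns per-site estimates (NaN where the
    denominator vanishes, e.g. monomorphic in both samples) and the mean
    as a ratio of sums over sites — the "weighted" estimate of vcftools.

    Sites with fewer than 2 non-missing genotypes in either sample are
    skipped.
    """
    if not a.sites[["chrom", "pos"]].equals(b.sites[["chrom", "pos"]]):
        raise ValueError("genotype matrices must share sites")
    r = 2  # number of populations
    comps = []
    for g in (a, b):
        called = g.calls != -1
        n_i = called.sum(axis=1).astype(float)
        alt = np.where(called, g.calls, 0).sum(axis=1)
        het = np.where(called, g.calls == 1, False).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), np.nan)
            h_i = np.where(n_i > 0, het / np.maximum(n_i, 1), np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    ok = (n1 >= 2) & (n2 >= 2)

    n_bar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        comp_a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        comp_b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        comp_c = h_bar / 2.0

    denom = comp_a + comp_b + comp_c
    informative = ok & np.isfinite(denom) & (denom != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_site = np.where(informative, comp_a / np.where(informative, denom, 1.0), np.nan)
    num_sum = comp_a[informative].sum()
    den_sum = denom[informative].sum()
    mean = float(num_sum / den_sum) if den_sum > 0 else float("nan")
    return per_site, mean


def mean_fst_over_replicates(
    p: SimParams, n_replicates: int, pops: str = "brahman_taurine"
) -> tuple[float, list[float]]:
    """Mean WC FST over seeded replicate simulations.

    ``pops`` selects which pair is compared: ``brahman_taurine`` (the
    published comparison) or ``founders`` (taurine vs indicine).
    """
    vals = []
    for rep in range(n_replicates):
        out = simulate_breed_formation(replace(p, seed=p.seed + 7919 * rep))
        if pops == "founders":
            _, fst = weir_cockerham_fst(out.taurine, out.indicine)
        else:
            _, fst = weir_cockerham_fst(out.brahman, out.taurine)
        vals.append(fst)
    return float(np.mean(vals)), vals


def tune_divergence(
    target_fst: float,
    p: SimParams,
    tolerance: float = 0.02,
    n_replicates: int = 3,
    max_iter: int = 10,
    pops: str = "brahman_taurine",
) -> tuple[int, float]:
    """Bisection on ``divergence_gens`` until the mean FST hits a target.

    Returns (tuned divergence_gens, achieved mean FST). A target of 0
    needs no divergence at all. The achieved FST is stochastic, so the
    search stops once |achieved − target| <= tolerance or the bracket
    collapses.
    """
    if target_fst < 0:
        raise ValueError("target FST must be non-negative")
    if target_fst == 0:
        return 0, 0.0
    lo, hi = 0, max(p.divergence_gens, 1)
    f_hi, _ = mean_fst_over_replicates(replace(p, divergence_gens=hi), n_replicates, pops)
    expand = 0
    while f_hi < target_fst and expand < 6:
        hi *= 2
        f_hi, _ = mean_fst_over_replicates(replace(p, divergence_gens=hi), n_replicates, pops)
        expand += 1
    best_t, best_f = hi, f_hi
    for _ in range(max_iter):
        mid = (lo + hi) // 2
        if mid in (lo, hi):
            break
        f_mid, _ = mean_fst_over_replicates(
            replace(p, divergence_gens=mid), n_replicates, pops
        )
        if abs(f_mid - target_fst) < abs(best_f - target_fst):
            best_t, best_f = mid, f_mid
        if abs(f_mid - target_fst) <= tolerance:
            return mid, f_mid
        if f_mid < target_fst:
            lo = mid
        else:
            hi = mid
    return best_t, best_f
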