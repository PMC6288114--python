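"""Synthetic inputs for every pipeline stage.

The generator emulates, at desk scale, the data the analysis consumes:

* two reference populations diverged to a target FST (Balding–Nichols
  allele-frequency model around a shared ancestral frequency);
* an admixed "graded-up" cohort whose genomes are mosaics of tracts from
  the two founders, with the ground-truth tract set retained so window
  classification can be scored against truth;
* planted fixed alternate-allele sites;
* windowed read-depth profiles carrying duplications / deletions such as
  the candidate polled-locus structural variants, and aligned-read
  intervals for deletion spanning-read checks.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .coverage_polled import DepthProfile
from .variant_io import MISSING, FrequencyTable, GenotypeMatrix

TAURINE = "taurine"
INDICINE = "indicine"

_BASES = np.array(list("ACGT"))


@dataclass
class FounderModel:
    """Two reference panels diverged from one ancestral population.

    ``divergence_fst`` is the Balding–Nichols F: each daughter
    population's site frequency is Beta-distributed around the ancestral
    frequency with variance F·p·(1−p), so the expected pairwise FST of
    the daughters approximates F.
    """

    n_sites: int
    divergence_fst: float
    seed: int
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    chrom: str = "1"
    chrom_length: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not (0 <= self.divergence_fst < 1):
            raise ValueError("divergence_fst must lie in [0, 1)")
        if self.n_sites > self.chrom_length:
            raise ValueError("more sites than base pairs")


@dataclass
class MosaicSpec:
    """An admixed cohort whose haplotypes are tilings of ancestry tracts."""

    chrom_length: int
    taurine_target_fraction: float
    tract_mean_bp: float
    n_animals: int
    seed: int
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.taurine_target_fraction <= 1):
            raise ValueError("taurine_target_fraction must lie in [0, 1]")
        if self.tract_mean_bp <= 0 or self.chrom_length < 1 or self.n_animals < 1:
            raise ValueError("invalid mosaic dimensions")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")


Tract = tuple[int, int, str]  # (start, end, origin), 1-based inclusive


@dataclass
class AncestryTractSet:
    """Ground-truth ancestry tracts per animal haplotype.

    ``tracts[animal]`` is a pair of ordered tract lists (one per
    haplotype); each tract is (start, end, origin) in 1-based inclusive
    coordinates, and the tracts of a haplotype tile [1, chrom_length].
    """

    chrom: str
    chrom_length: int
    tracts: dict[str, tuple[list[Tract], list[Tract]]]

    def __post_init__(self) -> None:
        for animal, haps in self.tracts.items():
            for hap in haps:
                pos = 1
                for start, end, origin in hap:
                    if start != pos or end < start or origin not in (TAURINE, INDICINE):
                        raise ValueError(f"tracts of {animal} do not tile the chromosome")
                    pos = end + 1
                if pos != self.chrom_length + 1:
                    raise ValueError(f"tracts of {animal} do not reach chrom_length")

    def realized_taurine_fraction(self) -> float:
        """Taurine bp over total bp, pooled over all haplotypes."""
        tau = total = 0
        for haps in self.tracts.values():
            for hap in haps:
                for start, end, origin in hap:
                    length = end - start + 1
                    total += length
                    if origin == TAURINE:
                        tau += length
        return tau / total if total else 0.0

    def window_taurine_fraction(self, animal: str, window: int) -> np.ndarray:
        """Per fixed window, fraction of the animal's bp that is taurine."""
        n_win = int(np.ceil(self.chrom_length / window))
        tau = np.zeros(n_win)
        for hap in self.tracts[animal]:
            for start, end, origin in hap:
                if origin != TAURINE:
                    continue
                w0, w1 = (start - 1) // window, (end - 1) // window
                for w in range(w0, w1 + 1):
                    lo = max(start, w * window + 1)
                    hi = min(end, (w + 1) * window)
                    tau[w] += hi - lo + 1
        sizes = np.full(n_win, window, dtype=float)
        sizes[-1] = self.chrom_length - (n_win - 1) * window
        return tau / (2 * sizes)

    def to_bed_frame(self) -> pd.DataFrame:
        """Tracts as a BED-like table (1-based inclusive, documented)."""
        rows = []
        for animal, haps in self.tracts.items():
            for h, hap in enumerate(haps):
                for start, end, origin in hap:
                    rows.append((self.chrom, start, end, animal, h, origin))
        return pd.DataFrame(
            rows, columns=["CHROM", "START", "END", "ANIMAL", "HAPLOTYPE", "ORIGIN"]
        )


@dataclass
class StructuralVariantSpec:
    """A planted duplication or deletion for depth-profile simulation."""

    kind: Literal["duplication", "deletion"]
    start: int
    end: int
    copies_per_haplotype: int = 1
    genotype: Literal["het", "hom"] = "hom"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("start must not exceed end")
        if self.kind == "duplication" and self.copies_per_haplotype < 1:
            raise ValueError("duplication needs >= 1 extra copy per haplotype")
        if self.kind not in ("duplication", "deletion"):
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    def copy_factor(self) -> float:
        """Expected depth multiplier over the SV footprint.

        Extra copies are carried on 1 (het) or 2 (hom) haplotypes; the
        factor is 1 + carried/2 for duplications, and 1 − deleted
        haplotype fraction for deletions.
        """
        n_hap = 2 if self.genotype == "hom" else 1
        if self.kind == "duplication":
            return 1.0 + self.copies_per_haplotype * n_hap / 2.0
        return 1.0 - n_hap / 2.0


# ---------------------------------------------------------------------------
# Founder frequencies (Balding–Nichols)
# ---------------------------------------------------------------------------

def _random_sites(rng: np.random.Generator, model: FounderModel) -> pd.DataFrame:
    pos = np.sort(
        rng.choice(model.chrom_length, size=model.n_sites, replace=False) + 1
    )
    ref_i = rng.integers(0, 4, size=model.n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=model.n_sites)) % 4
    return pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
        }
    )


def draw_founder_frequencies(model: FounderModel) -> tuple[FrequencyTable, FrequencyTable]:
    """Draw matched taurine / indicine frequency tables.

    Ancestral frequencies are uniform on [ancestral_low, ancestral_high];
    each daughter frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with
    F = divergence_fst. F = 0 degenerates to both daughters equal to the
    ancestral frequency exactly.
    """
    rng = np.random.default_rng(model.seed)
    sites = _random_sites(rng, model)
    p = rng.uniform(model.ancestral_low, model.ancestral_high, size=model.n_sites)
    F = model.divergence_fst
    if F == 0:
        af1, af2 = p.copy(), p.copy()
    else:
        scale = (1.0 - F) / F
        af1 = rng.beta(p * scale, (1.0 - p) * scale)
        af2 = rng.beta(p * scale, (1.0 - p) * scale)
    return FrequencyTable(sites.copy(), af1), FrequencyTable(sites.copy(), af2)


# ---------------------------------------------------------------------------
# Mosaic cohort
# ---------------------------------------------------------------------------

def _draw_haplotype_tracts(
    rng: np.random.Generator, spec: MosaicSpec
) -> list[Tract]:
    """Tile [1, chrom_length] with exponential-length tracts.

    Tract origins are i.i.d. taurine with probability
    ``taurine_target_fraction`` (Markovian ancestry switching), so the
    expected taurine bp fraction equals the target.
    """
    tracts: list[Tract] = []
    pos = 1
    while pos <= spec.chrom_length:
        length = max(1, int(np.ceil(rng.exponential(spec.tract_mean_bp))))
        end = min(pos + length - 1, spec.chrom_length)
        origin = TAURINE if rng.random() < spec.taurine_target_fraction else INDICINE
        # merge with previous tract when origins agree, keeping tracts maximal
        if tracts and tracts[-1][2] == origin:
            tracts[-1] = (tracts[-1][0], end, origin)
        else:
            tracts.append((pos, end, origin))
        pos = end + 1
    return tracts


def simulate_mosaic_cohort(
    spec: MosaicSpec, founders: tuple[FrequencyTable, FrequencyTable]
) -> tuple[GenotypeMatrix, AncestryTractSet]:
    """Simulate an admixed cohort from two founder frequency tables.

    ``founders`` is (taurine, indicine). Each haplotype is a tract tiling;
    the allele at a site is Bernoulli with the frequency of the tract's
    origin population; genotypes are haplotype sums. Missing calls are
    injected at ``spec.missing_rate``.
    """
    tau, ind = founders
    if not tau.sites[["chrom", "pos"]].equals(ind.sites[["chrom", "pos"]]):
        raise ValueError("founder tables must share site coordinates")
    if int(tau.sites["pos"].max()) > spec.chrom_length:
        raise ValueError("founder sites fall outside the chromosome")
    rng = np.random.default_rng(spec.seed)
    pos = tau.sites["pos"].to_numpy()
    chrom = str(tau.sites["chrom"].iloc[0])
    animals = [f"animal_{i+1:03d}" for i in range(spec.n_animals)]
    calls = np.zeros((len(pos), spec.n_animals), dtype=np.int8)
    tract_map: dict[str, tuple[list[Tract], list[Tract]]] = {}
    for a, animal in enumerate(animals):
        haps = []
        geno = np.zeros(len(pos), dtype=np.int8)
        for _ in range(2):
            tracts = _draw_haplotype_tracts(rng, spec)
            haps.append(tracts)
            hap_af = np.empty(len(pos))
            for start, end, origin in tracts:
                in_tract = (pos >= start) & (pos <= end)
                src = tau if origin == TAURINE else ind
                hap_af[in_tract] = src.af[in_tract]
            geno += (rng.random(len(pos)) < hap_af).astype(np.int8)
        calls[:, a] = geno
        tract_map[animal] = (haps[0], haps[1])
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING
    g = GenotypeMatrix(tau.sites.copy(), animals, calls)
    truth = AncestryTractSet(chrom, spec.chrom_length, tract_map)
    return g, truth


def plant_fixed_differences(
    genotypes: GenotypeMatrix,
    taurus_freqs: FrequencyTable,
    n_fixed: int,
    seed: int,
) -> tuple[GenotypeMatrix, FrequencyTable, pd.DataFrame]:
    """Force ``n_fixed`` random sites to hom-alt in every animal.

    The chosen sites are removed from the taurine table, so they satisfy
    the fixed-alternate definition (hom-alt in every cohort animal and
    absent from the comparison panel). Returns the modified genotype
    matrix, the pruned taurine table and the chosen site rows.
    """
    if n_fixed < 0 or n_fixed > genotypes.n_sites:
        raise ValueError("n_fixed must lie in [0, n_sites]")
    if n_fixed == 0:
        return genotypes, taurus_freqs, genotypes.sites.iloc[:0].copy()
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(genotypes.n_sites, size=n_fixed, replace=False))
    calls = genotypes.calls.copy()
    calls[idx, :] = 2
    chosen = genotypes.sites.iloc[idx].reset_index(drop=True)
    chosen_keys = set(map(tuple, chosen[["chrom", "pos"]].itertuples(index=False)))
    keep = [
        i
        for i, key in enumerate(
            map(tuple, taurus_freqs.sites[["chrom", "pos"]].itertuples(index=False))
        )
        if key not in chosen_keys
    ]
    pruned = FrequencyTable(
        taurus_freqs.sites.iloc[keep].reset_index(drop=True), taurus_freqs.af[keep]
    )
    return (
        GenotypeMatrix(genotypes.sites.copy(), list(genotypes.animals), calls),
        pruned,
        chosen,
    )


# ---------------------------------------------------------------------------
# Depth profiles and reads
# ---------------------------------------------------------------------------

def expected_window_depth(
    mean_depth: float,
    interval: tuple[int, int],
    window: int,
    svs: Sequence[StructuralVariantSpec] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-window read-base counts given planted SVs.

    Returns (window starts, expected counts). The expectation is
    mean_depth × window_size × copy factor, with the copy factor averaged
    over the fraction of the window each SV overlaps.
    """
    start, end = interval
    if end < start:
        raise ValueError("empty interval")
    n_win = (end - start + 1) // window
    if (end - start + 1) % window:
        n_win += 1
    if n_win < 2:
        raise ValueError("window must split the interval into >= 2 windows")
    starts = start + window * np.arange(n_win)
    ends = np.minimum(starts + window - 1, end)
    sizes = (ends - starts + 1).astype(float)
    factor = np.ones(n_win)
    for sv in svs:
        lo = np.maximum(starts, sv.start)
        hi = np.minimum(ends, sv.end)
        overlap = np.clip(hi - lo + 1, 0, None) / sizes
        factor += (sv.copy_factor() - 1.0) * overlap
    return starts, mean_depth * sizes * np.clip(factor, 0.0, None)


def simulate_depth_profile(
    mean_depth: float,
    interval: tuple[int, int],
    window: int,
    svs: Sequence[StructuralVariantSpec],
    seed: int,
    chrom: str = "1",
    group: str = "",
) -> DepthProfile:
    """Poisson per-window read-base counts around planted SVs."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    starts, expected = expected_window_depth(mean_depth, interval, window, svs)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(float)
    return DepthProfile(chrom, starts, counts, window, group=group,
                        partial_last=(interval[1] - interval[0] + 1) % window != 0)


def simulate_reads(
    mean_depth: float,
    interval: tuple[int, int],
    read_length: int,
    seed: int,
    deletion: StructuralVariantSpec | None = None,
    chrom: str = "1",
    animal: str = "animal_001",
) -> pd.DataFrame:
    """Simulate aligned read intervals at uniform coverage.

    Read starts are Poisson along the interval at rate mean_depth /
    read_length per bp. When a homozygous ``deletion`` is given, reads
    overlapping the deleted sequence cannot be aligned contiguously and
    are split at the deletion (emulating clipped alignments), so no read
    spans it; a heterozygous deletion removes spanning reads from half
    the haplotypes.
    """
    if mean_depth <= 0 or read_length < 1:
        raise ValueError("invalid coverage geometry")
    rng = np.random.default_rng(seed)
    start, end = interval
    rate = mean_depth / read_length
    n_reads = rng.poisson(rate * (end - start + 1))
    r_start = rng.integers(start, end + 1, size=n_reads)
    r_end = np.minimum(r_start + read_length - 1, end)
    hap = rng.integers(0, 2, size=n_reads)
    rows = []
    for s, e, h in zip(r_start, r_end, hap):
        if deletion is not None and deletion.kind == "deletion":
            carried = deletion.genotype == "hom" or h == 0
            if carried and s <= deletion.start and e >= deletion.end:
                # alignment breaks at the missing sequence: keep the clipped parts
                if deletion.start - 1 >= s:
                    rows.append((chrom, int(s), int(deletion.start - 1), animal))
                if e >= deletion.end + 1:
                    rows.append((chrom, int(deletion.end + 1), int(e), animal))
                continue
        rows.append((chrom, int(s), int(e), animal))
    return pd.DataFrame(rows, columns=["CHROM", "START", "END", "ANIMAL"])
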