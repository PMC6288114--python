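"""Genotype and allele-frequency containers plus the standard-format IO.

The pipeline works from two in-memory tables:

* :class:`GenotypeMatrix` — diploid biallelic SNP calls for the admixed
  cohort, coded 0 (hom-ref) / 1 (het) / 2 (hom-alt) / -1 (missing).
* :class:`FrequencyTable` — per-site alternate-allele frequency of one
  reference population (e.g. a pure *Bos taurus* or *Bos indicus* panel).

Coordinates are 1-based inclusive (VCF convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SITE_COLS = ["chrom", "pos", "ref", "alt"]


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a site table (sorted, unique, 1-based)."""
    missing = [c for c in SITE_COLS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    sites = sites.reset_index(drop=True)
    if (sites["pos"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    key = sites[["chrom", "pos"]]
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index
    if not (order == np.arange(len(sites))).all():
        raise ValueError("sites must be sorted by (chrom, pos)")
    if key.duplicated().any() or sites[SITE_COLS].duplicated().any():
        raise ValueError("duplicate (chrom, pos) entries in site table")
    return sites


@dataclass
class GenotypeMatrix:
    """Biallelic SNP × animal diploid call matrix.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, ref, alt`` sorted by
        (chrom, pos), unique coordinates.
    animals
        Ordered animal identifiers (columns of ``calls``).
    calls
        int8 array of shape (n_sites, n_animals); -1 encodes a missing call.
    """

    sites: pd.DataFrame
    animals: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.animals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.animals)} animals"
            )
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def site_keys(self) -> set[tuple]:
        """Sites as a set of (chrom, pos, ref, alt) tuples."""
        return set(map(tuple, self.sites[SITE_COLS].itertuples(index=False)))

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given (sorted) site row indices."""
        return GenotypeMatrix(
            self.sites.iloc[idx].reset_index(drop=True),
            list(self.animals),
            self.calls[idx],
        )


@dataclass
class FrequencyTable:
    """Per-site alternate-allele frequency for one reference population."""

    sites: pd.DataFrame
    af: np.ndarray

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        self.af = np.asarray(self.af, dtype=float)
        if self.af.shape != (len(self.sites),):
            raise ValueError("af length does not match site table")
        if ((self.af < 0) | (self.af > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> set[tuple]:
        return set(map(tuple, self.sites[SITE_COLS].itertuples(index=False)))

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        out["af"] = self.af
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencyTable":
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return cls(df[SITE_COLS], df["af"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.columns = ["CHROM", "POS", "REF", "ALT", "AF"]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
        df.columns = [c.lower() for c in df.columns]
        return cls.from_frame(df)


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNPs are skipped (count logged).
    ``./.`` genotypes become missing. Requires a GT FORMAT field.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    if "GT" not in {f for f in _format_ids(vcf.raw_header)}:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    animals = list(vcf.samples)
    rows: list[tuple] = []
    calls: list[np.ndarray] = []
    skipped = 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1:
            skipped += 1
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        calls.append(g)
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    sites = pd.DataFrame(rows, columns=SITE_COLS)
    mat = (
        np.vstack(calls) if calls else np.empty((0, len(animals)), dtype=np.int8)
    )
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(sites.iloc[order].reset_index(drop=True), animals, mat[order])


def _format_ids(raw_header: str) -> Iterable[str]:
    for line in raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            yield line.split("ID=", 1)[1].split(",", 1)[0]


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path, contigs: dict[str, int] | None = None) -> None:
    """Write a GT-only VCF 4.2."""
    if contigs is None:
        contigs = {
            c: int(g.sites.loc[g.sites["chrom"] == c, "pos"].max())
            for c in g.sites["chrom"].unique()
        }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaicmap\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.animals)
            + "\n"
        )
        for i, (chrom, pos, ref, alt) in enumerate(
            g.sites[SITE_COLS].itertuples(index=False)
        ):
            gts = "\t".join(_GT_STR[int(c)] for c in g.calls[i])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Derived tables
# ---------------------------------------------------------------------------

def compute_allele_frequencies(g: GenotypeMatrix) -> FrequencyTable:
    """Alternate-allele frequency per site: (het + 2*hom-alt) / (2*called).

    Sites where every animal is missing are dropped.
    """
    calls = g.calls
    called = calls != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, calls, 0).sum(axis=1)
    keep = n_called > 0
    if (~keep).any():
        logger.info(
            "compute_allele_frequencies: dropped %d all-missing sites", int((~keep).sum())
        )
    af = alt[keep] / (2.0 * n_called[keep])
    return FrequencyTable(g.sites.loc[keep].reset_index(drop=True), af)


def intersect_variant_sets(
    a: Iterable[tuple], b: Iterable[tuple], c: Iterable[tuple]
) -> dict[str, int]:
    """Counts of the 7 exclusive Venn regions of three variant sets.

    Sites are keyed by (chrom, pos, ref, alt). Keys of the result:
    ``a``, ``b``, ``c`` (exclusive to one set), ``ab``, ``ac``, ``bc``
    (exactly two), ``abc`` (all three).
    """
    sa, sb, sc = set(a), set(b), set(c)
    abc = sa & sb & sc
    ab = (sa & sb) - abc
    ac = (sa & sc) - abc
    bc = (sb & sc) - abc
    return {
        "a": len(sa - sb - sc),
        "b": len(sb - sa - sc),
        "c": len(sc - sa - sb),
        "ab": len(ab),
        "ac": len(ac),
        "bc": len(bc),
        "abc": len(abc),
    }


def join_on_sites(g: GenotypeMatrix, f: FrequencyTable) -> tuple[GenotypeMatrix, np.ndarray]:
    """Inner-join genotypes with a frequency table on genomic location.

    The join key is (chrom, pos); sites whose ref/alt alleles disagree
    between the two tables are dropped and counted, never allele-flipped.

    Returns the genotype subset (site order preserved) and the aligned
    frequency vector.
    """
    left = g.sites.reset_index(names="_gi")
    right = f.to_frame().rename(columns={"ref": "ref_f", "alt": "alt_f"})
    merged = left.merge(right, on=["chrom", "pos"], how="inner")
    if merged.empty:
        logger.warning("join_on_sites: no shared coordinates between inputs")
        return g.take_sites(np.array([], dtype=int)), np.array([])
    ok = (merged["ref"] == merged["ref_f"]) & (merged["alt"] == merged["alt_f"])
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("join_on_sites: dropped %d allele-mismatched sites", n_bad)
    merged = merged.loc[ok]
    idx = merged["_gi"].to_numpy()
    return g.take_sites(idx), merged["af"].to_numpy()
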