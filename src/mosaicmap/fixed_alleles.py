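"""Fixed alternate alleles and annotation-class statistics.

A site is "fixed alternate" when every cohort animal is homozygous for
the alternative allele and the site is absent from the comparison
(taurine) panel. Fixed sites are summarised per functional annotation
class: the class count, its percent of the total, and the signed
symmetric percent difference against the genome-wide proportion of that
class. A Pearson chi-square compares the fixed-class distribution with
expectations proportional to the genome-wide class counts.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variant_io import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)


def find_fixed_alt(
    g: GenotypeMatrix, taurus_sites: set[tuple], strict: bool = False
) -> pd.DataFrame:
    """Sites hom-alt in every animal and absent from the taurine panel.

    ``taurus_sites`` is keyed by (chrom, pos) or (chrom, pos, ref, alt);
    both key shapes are accepted. By default missing calls are tolerated
    as long as every *called* animal is hom-alt; ``strict=True``
    additionally requires zero missing calls.
    """
    if g.n_animals == 0:
        raise ValueError("empty cohort")
    calls = g.calls
    if strict:
        all_hom = (calls == 2).all(axis=1)
    else:
        called = calls != MISSING
        all_hom = ((calls == 2) | ~called).all(axis=1) & called.any(axis=1)
    key_len = len(next(iter(taurus_sites))) if taurus_sites else 2
    cols = ["chrom", "pos", "ref", "alt"][:key_len]
    keys = list(map(tuple, g.sites[cols].itertuples(index=False)))
    absent = np.array([k not in taurus_sites for k in keys])
    return g.sites.loc[all_hom & absent].reset_index(drop=True)


def class_summary(
    fixed_counts: pd.Series, genome_percents: pd.Series | None = None
) -> pd.DataFrame:
    """Annotation-class table: count, percent of total, percent difference.

    ``fixed_counts`` maps class label -> fixed-variant count.
    ``genome_percents`` (optional) maps class label -> genome-wide percent
    of all variants in that class; when given, the signed symmetric
    percent difference of the fixed percent against it is added.
    Percent columns are rounded to 3 decimals (table convention).
    """
    if (fixed_counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(fixed_counts.sum())
    out = pd.DataFrame(
        {
            "annotation": fixed_counts.index,
            "n_snp": fixed_counts.to_numpy().astype(int),
        }
    )
    out["percent_of_total"] = (100.0 * out["n_snp"] / total).round(3)
    if genome_percents is not None:
        gw = out["annotation"].map(genome_percents)
        out["percent_difference"] = [
            round(symmetric_percent_difference(a, b), 3) if pd.notna(b) else np.nan
            for a, b in zip(out["percent_of_total"], gw)
        ]
    return out


def symmetric_percent_difference(a: float, b: float) -> float:
    """Signed symmetric percent difference 100*(a-b) / ((a+b)/2)."""
    if a + b == 0:
        raise ValueError("undefined for a + b = 0")
    return 100.0 * (a - b) / ((a + b) / 2.0)


def chi_square_class_enrichment(
    fixed_counts: pd.Series,
    genome_counts: pd.Series,
    pool_threshold: float = 5.0,
) -> tuple[float, int, float]:
    """Pearson chi-square of fixed-class counts vs genome-wide proportions.

    Expected counts are the total number of fixed sites distributed
    proportionally to the genome-wide class counts. Classes with an
    expected count below ``pool_threshold`` are pooled into "other"
    (logged). Returns (statistic, degrees of freedom, p-value).
    """
    labels = fixed_counts.index
    if set(labels) != set(genome_counts.index):
        raise ValueError("fixed and genome-wide counts must share class labels")
    genome_counts = genome_counts.reindex(labels).astype(float)
    observed = fixed_counts.astype(float)
    total = observed.sum()
    expected = total * genome_counts / genome_counts.sum()
    small = expected < pool_threshold
    if small.any():
        logger.info(
            "chi_square_class_enrichment: pooling %d small classes into 'other'",
            int(small.sum()),
        )
        observed = pd.concat(
            [observed[~small], pd.Series({"other": observed[small].sum()})]
        )
        expected = pd.concat(
            [expected[~small], pd.Series({"other": expected[small].sum()})]
        )
    stat, p = sps.chisquare(observed.to_numpy(), expected.to_numpy())
    df = len(observed) - 1
    return float(stat), int(df), float(p)


# ---------------------------------------------------------------------------
# Published annotation-class table (shipped as package data)
# ---------------------------------------------------------------------------

def load_published_class_counts() -> pd.DataFrame:
    """Annotation-class counts of the 20,917 fixed Brahman alternate-allele
    SNPs, with the genome-wide percentages known for the intergenic,
    intron and missense classes. Percent columns are recomputed from the
    counts by :func:`class_summary`, not stored."""
    path = resources.files("mosaicmap.data") / "brahman_fixed_annotation_counts.tsv"
    return pd.read_csv(path, sep="\t")


def annotations_for_sites(
    sites: pd.DataFrame, annotations: pd.DataFrame
) -> pd.Series:
    """Class counts for a site list given a (CHROM, POS, CLASS) table."""
    ann = annotations.rename(
        columns={"CHROM": "chrom", "POS": "pos", "CLASS": "ann_class"}
    )
    merged = sites.merge(ann, on=["chrom", "pos"], how="left")
    merged["ann_class"] = merged["ann_class"].fillna("Unknown")
    return merged["ann_class"].value_counts().sort_index()
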