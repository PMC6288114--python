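"""Permutation null for annotation-keyword enrichment.

The observed gene set (e.g. all genes inside the top introgression
windows) carries a set of annotation keywords. To ask whether a keyword
could show up by chance, random gene sets of the same size are drawn
from the gene universe; a keyword "occurs" in a permutation if any
sampled gene carries it. Keywords never seen across the permutations are
flagged, and every observed keyword gets an add-one empirical p-value
(count + 1) / (n_perm + 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GeneAnnotationMap = dict[str, set[str]]


def read_gene_annotation_map(path: str | Path) -> GeneAnnotationMap:
    """Read a tab-delimited (GENE, KEYWORD) table into a gene -> keywords map."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.upper() for c in df.columns]
    out: GeneAnnotationMap = {}
    for gene, kw in zip(df["GENE"], df["KEYWORD"]):
        out.setdefault(str(gene), set()).add(str(kw))
    return out


def keywords_of(genes: set[str], annotation_map: GeneAnnotationMap) -> set[str]:
    """Union of keywords carried by a gene set."""
    out: set[str] = set()
    for g in genes:
        out |= annotation_map.get(g, set())
    return out


def permutation_keyword_null(
    universe: list[str],
    set_size: int,
    annotation_map: GeneAnnotationMap,
    n_perm: int = 100,
    seed: int = 0,
    count_genes: bool = False,
) -> pd.Series:
    """Keyword occurrence counts across random same-size gene sets.

    Each permutation samples ``set_size`` genes from ``universe`` without
    replacement. By default a keyword scores once per permutation in
    which any sampled gene carries it (binary occurrence), so counts lie
    in [0, n_perm]; ``count_genes=True`` instead accumulates the number
    of carrying genes.
    """
    universe = list(universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for _ in range(n_perm):
        sample = rng.choice(len(universe), size=set_size, replace=False)
        if count_genes:
            for i in sample:
                for kw in annotation_map.get(universe[i], ()):
                    counts[kw] = counts.get(kw, 0) + 1
        else:
            seen: set[str] = set()
            for i in sample:
                seen |= annotation_map.get(universe[i], set())
            for kw in seen:
                counts[kw] = counts.get(kw, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def never_observed_keywords(
    observed: set[str], null_counts: pd.Series, n_perm: int = 100
) -> pd.DataFrame:
    """Empirical p-values for observed keywords against the null.

    Keywords absent from every permutation are flagged
    ``never_observed``; all observed keywords receive the add-one
    empirical p-value (null count + 1) / (n_perm + 1), which lies in
    [1/(n_perm+1), 1].
    """
    rows = []
    for kw in sorted(observed):
        c = int(null_counts.get(kw, 0))
        rows.append((kw, c, c == 0, (c + 1) / (n_perm + 1)))
    return pd.DataFrame(
        rows, columns=["keyword", "null_count", "never_observed", "empirical_p"]
    )


def genes_in_windows(
    gene_coords: pd.DataFrame, windows: pd.DataFrame
) -> set[str]:
    """Genes overlapping any of the given windows.

    ``gene_coords`` columns: GENE, CHROM, START, END (1-based inclusive);
    ``windows`` columns: chrom, start, end.
    """
    hits: set[str] = set()
    for chrom, grp in windows.groupby("chrom"):
        genes_c = gene_coords[gene_coords["CHROM"].astype(str) == str(chrom)]
        if genes_c.empty:
            continue
        for _, win in grp.iterrows():
            sel = (genes_c["START"] <= win["end"]) & (genes_c["END"] >= win["start"])
            hits |= set(genes_c.loc[sel, "GENE"].astype(str))
    return hits
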