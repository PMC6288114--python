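"""Per-SNP and per-window differentiation of one individual vs a reference.

The core statistic compares one animal's diploid call (encoded 0 / 0.5 / 1)
with a reference population's alternate-allele frequency ``p_ref`` as an
FST-like ratio::

    Hs = p_ref (1 - p_ref) + p_ind (1 - p_ind)
    Ht = 2 pbar (1 - pbar),   pbar = (p_ref + p_ind) / 2
    b  = (Ht - Hs) / Ht

``b`` is 0 when the animal looks like a random draw from the reference and
1 at a fixed difference; it is undefined (excluded downstream) when
Ht = 0, i.e. the animal and the reference agree monomorphically. Since
Ht - Hs expands to (p_ref - p_ind)^2 / 2, the statistic equals
(p_ref - p_ind)^2 / (2 Ht): symmetric and non-negative wherever defined.

Per-SNP values are averaged in fixed, adjacent, non-overlapping windows
(default 250 kb, anchored at position 1). Running the statistic against a
taurine and an indicine reference panel and comparing the two window
averages localises the ancestry of each window of the mosaic genome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import FrequencyTable, GenotypeMatrix, MISSING, join_on_sites

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 250_000
DEFAULT_MIN_SNPS = 10


def bosind_values(p_ref: np.ndarray, p_ind: np.ndarray) -> np.ndarray:
    """Vectorised per-SNP statistic; NaN marks undefined sites (Ht = 0)."""
    p_ref = np.asarray(p_ref, dtype=float)
    p_ind = np.asarray(p_ind, dtype=float)
    hs = p_ref * (1.0 - p_ref) + p_ind * (1.0 - p_ind)
    pbar = 0.5 * (p_ref + p_ind)
    ht = 2.0 * pbar * (1.0 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return out


def bosind_snp(p_ref: float, p_ind: float) -> float:
    """Scalar form; returns NaN when undefined (both sides fixed and equal)."""
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError("reference frequency outside [0, 1]")
    if p_ind not in (0.0, 0.5, 1.0):
        raise ValueError("individual call must be encoded 0, 0.5 or 1")
    return float(bosind_values(np.array([p_ref]), np.array([p_ind]))[0])


def window_index(pos: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """0-based fixed-window index of a 1-based position."""
    return (np.asarray(pos, dtype=np.int64) - 1) // window


@dataclass
class WindowStatTable:
    """Per animal × window averaged statistics against both references.

    ``windows`` columns: animal, chrom, win_index, start, end,
    bosind_tau, bosind_ind, n_snp_tau, n_snp_ind, callable_tau,
    callable_ind. ``per_animal_global`` holds the pooled per-SNP means
    (over all defined SNPs, not window means).
    """

    window: int
    min_snps: int
    windows: pd.DataFrame
    per_animal_global: pd.DataFrame

    def callable_windows(self) -> pd.DataFrame:
        w = self.windows
        return w[w["callable_tau"] & w["callable_ind"]]


def _per_reference_window_stats(
    genotypes: GenotypeMatrix,
    ref: FrequencyTable,
    window: int,
    label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window sums/counts and global sums of the statistic for one reference."""
    g, af = join_on_sites(genotypes, ref)
    n_sites, n_animals = g.calls.shape
    if n_sites == 0:
        empty = pd.DataFrame(
            columns=["animal", "chrom", "win_index", f"sum_{label}", f"n_snp_{label}"]
        )
        glob = pd.DataFrame(
            {"animal": genotypes.animals, f"gsum_{label}": 0.0, f"gn_{label}": 0}
        )
        return empty, glob
    p_ind = np.where(g.calls == MISSING, np.nan, g.calls / 2.0)  # (S, A)
    vals = bosind_values(af[:, None], p_ind)
    defined = ~np.isnan(vals)
    win = window_index(g.sites["pos"].to_numpy(), window)
    frame = pd.DataFrame(
        {
            "chrom": np.repeat(g.sites["chrom"].to_numpy(), n_animals),
            "win_index": np.repeat(win, n_animals),
            "animal": np.tile(np.array(g.animals, dtype=object), n_sites),
            "val": vals.ravel(),
        }
    )
    frame = frame.dropna(subset=["val"])
    agg = (
        frame.groupby(["animal", "chrom", "win_index"], sort=True)["val"]
        .agg(["sum", "size"])
        .reset_index()
        .rename(columns={"sum": f"sum_{label}", "size": f"n_snp_{label}"})
    )
    gsum = np.where(defined, vals, 0.0).sum(axis=0)
    gn = defined.sum(axis=0)
    glob = pd.DataFrame(
        {"animal": g.animals, f"gsum_{label}": gsum, f"gn_{label}": gn}
    )
    return agg, glob


def compute_window_stats(
    genotypes: GenotypeMatrix,
    ref_tau: FrequencyTable,
    ref_ind: FrequencyTable,
    window: int = DEFAULT_WINDOW,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> WindowStatTable:
    """Run the statistic against both references and average per window.

    Windows cover ``[i*window + 1, (i+1)*window]`` (1-based) per
    chromosome; a window with fewer than ``min_snps`` defined SNPs against
    a reference is flagged non-callable for that reference. Missing
    genotypes are skipped for that animal only.
    """
    tau_w, tau_g = _per_reference_window_stats(genotypes, ref_tau, window, "tau")
    ind_w, ind_g = _per_reference_window_stats(genotypes, ref_ind, window, "ind")
    merged = tau_w.merge(ind_w, on=["animal", "chrom", "win_index"], how="outer")
    for label in ("tau", "ind"):
        merged[f"n_snp_{label}"] = merged[f"n_snp_{label}"].fillna(0).astype(int)
        merged[f"sum_{label}"] = merged[f"sum_{label}"].fillna(0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            merged[f"bosind_{label}"] = np.where(
                merged[f"n_snp_{label}"] > 0,
                merged[f"sum_{label}"] / merged[f"n_snp_{label}"].clip(lower=1),
                np.nan,
            )
        merged[f"callable_{label}"] = merged[f"n_snp_{label}"] >= min_snps
    merged["start"] = merged["win_index"] * window + 1
    merged["end"] = (merged["win_index"] + 1) * window
    merged = merged.sort_values(["animal", "chrom", "win_index"]).reset_index(drop=True)
    glob = tau_g.merge(ind_g, on="animal", how="outer").fillna(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        glob["global_tau"] = np.where(
            glob["gn_tau"] > 0, glob["gsum_tau"] / glob["gn_tau"].clip(lower=1), np.nan
        )
        glob["global_ind"] = np.where(
            glob["gn_ind"] > 0, glob["gsum_ind"] / glob["gn_ind"].clip(lower=1), np.nan
        )
    cols = [
        "animal", "chrom", "win_index", "start", "end",
        "bosind_tau", "bosind_ind", "n_snp_tau", "n_snp_ind",
        "callable_tau", "callable_ind",
    ]
    return WindowStatTable(window, min_snps, merged[cols], glob)


def window_average(
    values: np.ndarray,
    positions: np.ndarray,
    window: int = DEFAULT_WINDOW,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> pd.DataFrame:
    """Average per-SNP values within fixed windows (one chromosome).

    NaN values (undefined SNPs) are excluded from both the mean and the
    SNP count; windows with fewer than ``min_snps`` defined SNPs are
    flagged non-callable.
    """
    positions = np.asarray(positions)
    if len(positions) > 1 and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted")
    values = np.asarray(values, dtype=float)
    win = window_index(positions, window)
    df = pd.DataFrame({"win_index": win, "val": values}).dropna()
    agg = df.groupby("win_index")["val"].agg(["mean", "size"]).reset_index()
    agg.columns = ["win_index", "bosind_avg", "n_snp"]
    agg["callable"] = agg["n_snp"] >= min_snps
    agg["start"] = agg["win_index"] * window + 1
    agg["end"] = (agg["win_index"] + 1) * window
    return agg


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _tie_break_taurine(chrom: pd.Series, win_index: pd.Series) -> np.ndarray:
    # exact ties carry no information; split deterministically by window
    # parity so the degenerate identical-reference case lands near 50/50
    return (win_index.to_numpy() % 2) == 0


def animal_composition(stats: WindowStatTable) -> pd.DataFrame:
    """Per-animal genome composition summary.

    Columns: the global per-SNP means against each reference and the
    fraction of callable windows whose taurine-side average is lower
    (exact ties split deterministically by window parity).
    """
    w = stats.callable_windows()
    if w.empty:
        frac = pd.Series(dtype=float)
    else:
        tau_like = w["bosind_tau"] < w["bosind_ind"]
        tie = w["bosind_tau"] == w["bosind_ind"]
        tau_like = tau_like | (tie & _tie_break_taurine(w["chrom"], w["win_index"]))
        frac = tau_like.groupby(w["animal"]).mean()
    out = stats.per_animal_global[["animal", "global_tau", "global_ind"]].copy()
    out["taurine_window_fraction"] = out["animal"].map(frac).fillna(np.nan)
    return out


def cohort_composition(stats: WindowStatTable) -> dict[str, float]:
    """Cohort-level summaries, labelled by how they aggregate.

    ``*_pooled`` pools per-SNP values over all animals; ``*_animal_mean``
    averages the per-animal global values.
    """
    g = stats.per_animal_global
    comp = animal_composition(stats)
    return {
        "global_tau_pooled": float(g["gsum_tau"].sum() / max(g["gn_tau"].sum(), 1)),
        "global_ind_pooled": float(g["gsum_ind"].sum() / max(g["gn_ind"].sum(), 1)),
        "global_tau_animal_mean": float(g["global_tau"].mean()),
        "global_ind_animal_mean": float(g["global_ind"].mean()),
        "taurine_window_fraction_mean": float(comp["taurine_window_fraction"].mean()),
    }


# ---------------------------------------------------------------------------
# Percent difference, top windows, heatmaps
# ---------------------------------------------------------------------------

def percent_difference(b_tau: np.ndarray, b_ind: np.ndarray) -> np.ndarray:
    """Signed symmetric percent difference 100*(b_ind - b_tau)/mean.

    Positive values mark taurine-like windows (lower differentiation from
    the taurine reference); NaN where either side is undefined or both
    are zero.
    """
    b_tau = np.asarray(b_tau, dtype=float)
    b_ind = np.asarray(b_ind, dtype=float)
    denom = 0.5 * (b_tau + b_ind)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (b_ind - b_tau) / denom
    out = np.where(denom == 0, np.nan, out)
    return out


def window_percent_difference(stats: WindowStatTable) -> pd.DataFrame:
    """Per animal × window signed percent difference (NaN where no-call)."""
    w = stats.windows.copy()
    ok = w["callable_tau"] & w["callable_ind"]
    pct = percent_difference(w["bosind_tau"].to_numpy(), w["bosind_ind"].to_numpy())
    w["pct_diff"] = np.where(ok, pct, np.nan)
    return w[["animal", "chrom", "win_index", "start", "end", "pct_diff"]]


def cohort_window_means(stats: WindowStatTable) -> pd.DataFrame:
    """Cohort-mean window averages against each reference, then the
    percent difference of those means per window."""
    w = stats.callable_windows()
    agg = (
        w.groupby(["chrom", "win_index"], sort=True)[["bosind_tau", "bosind_ind"]]
        .mean()
        .reset_index()
    )
    agg["pct_diff"] = percent_difference(
        agg["bosind_tau"].to_numpy(), agg["bosind_ind"].to_numpy()
    )
    agg["start"] = agg["win_index"] * stats.window + 1
    agg["end"] = (agg["win_index"] + 1) * stats.window
    return agg


def select_top_windows(
    pct: pd.DataFrame, direction: str, fraction: float = 0.05
) -> pd.DataFrame:
    """Deterministically select the most extreme callable windows.

    ``direction='taurine'`` takes the largest positive percent
    differences, ``'indicine'`` the most negative. Exactly
    ``ceil(fraction * n_callable)`` windows are returned; ties are broken
    by (chrom, win_index).
    """
    if direction not in ("taurine", "indicine"):
        raise ValueError("direction must be 'taurine' or 'indicine'")
    callable_w = pct.dropna(subset=["pct_diff"]).copy()
    k = math.ceil(fraction * len(callable_w))
    ascending = direction == "indicine"
    ordered = callable_w.sort_values(
        ["pct_diff", "chrom", "win_index"],
        ascending=[ascending, True, True],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def heatmap_matrix(
    stats: WindowStatTable,
    chrom: str,
    birth_years: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Animals × windows matrix of percent differences for one chromosome.

    Rows are ordered by birth year (older animals first); animals with no
    recorded year are placed last (logged). Red/high values mark taurine
    introgression under the sign convention of :func:`percent_difference`.
    """
    pct = window_percent_difference(stats)
    pct = pct[pct["chrom"] == chrom]
    mat = pct.pivot(index="animal", columns="win_index", values="pct_diff")
    birth_years = birth_years or {}
    missing = [a for a in mat.index if a not in birth_years]
    if missing:
        logger.info("heatmap_matrix: %d animals without birth year placed last", len(missing))
    order = sorted(
        mat.index, key=lambda a: (a not in birth_years, birth_years.get(a, 0), a)
    )
    return mat.loc[order]


def render_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a heatmap matrix to a file (PDF/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Reds", interpolation="nearest")
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(matrix.index, fontsize=6)
    ax.set_xlabel("window index")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="percent difference (taurine-like > 0)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
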