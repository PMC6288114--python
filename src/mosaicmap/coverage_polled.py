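"""Windowed read-depth analysis around a candidate locus (polled scan).

Copy-number evidence at the polled locus comes from read counts in fixed
50 bp windows: a duplication raises coverage over its footprint (two-fold
for a homozygous single-extra-copy event), while the short replaced
sequence of the Celtic mutation shows up as an absence of reads that span
it. Profiles are standardised to SD-from-mean units within each group so
cohorts sequenced at different mean depths remain comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DepthProfile:
    """Per-window read counts over one genomic interval.

    ``starts`` are 1-based window start positions with a uniform step of
    ``window`` bp; ``counts[i]`` is the number of read-bases (or reads,
    depending on the source) assigned to ``[starts[i], starts[i]+window-1]``.
    """

    chrom: str
    starts: np.ndarray
    counts: np.ndarray
    window: int
    group: str = ""
    partial_last: bool = False

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.starts.shape != self.counts.shape:
            raise ValueError("starts and counts must align")
        if len(self.starts) > 1:
            step = np.diff(self.starts)
            if not (step == self.window).all():
                raise ValueError("window starts must advance by a uniform step")
        if (self.counts < 0).any():
            raise ValueError("window counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"CHROM": self.chrom, "WINDOW_START": self.starts, "COUNT": self.counts}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, group: str = "") -> "DepthProfile":
        df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
        starts = df["WINDOW_START"].to_numpy()
        window = int(starts[1] - starts[0]) if len(starts) > 1 else 50
        return cls(str(df["CHROM"].iloc[0]), starts, df["COUNT"].to_numpy(), window, group)


@dataclass
class DuplicationCall:
    """A run of windows with coverage elevated in carriers vs reference."""

    chrom: str
    start: int
    end: int  # 1-based inclusive
    n_windows: int
    fold_change: float
    mean_z_diff: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def window_depth(
    per_base: pd.DataFrame,
    region: tuple[str, int, int],
    window: int = 50,
    group: str = "",
) -> DepthProfile:
    """Aggregate a per-base depth track into fixed windows over a region.

    Parameters
    ----------
    per_base
        DataFrame with columns ``CHROM, POS, DEPTH`` (1-based positions),
        as produced by standard depth tools.
    region
        (chrom, start, end), 1-based inclusive.
    window
        Window size in bp; a partial terminal window is kept and flagged.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("empty region")
    sub = per_base[
        (per_base["CHROM"].astype(str) == str(chrom))
        & (per_base["POS"] >= start)
        & (per_base["POS"] <= end)
    ]
    span = end - start + 1
    n_win = int(np.ceil(span / window))
    starts = start + window * np.arange(n_win)
    counts = np.zeros(n_win)
    if len(sub):
        idx = ((sub["POS"].to_numpy() - start) // window).astype(int)
        np.add.at(counts, idx, sub["DEPTH"].to_numpy())
    partial = span % window != 0
    if partial:
        logger.info("window_depth: terminal window is partial (%d bp)", span % window)
    return DepthProfile(str(chrom), starts, counts, window, group, partial_last=partial)


def standardize_profile(p: DepthProfile) -> np.ndarray:
    """Counts expressed as SDs from the regional mean (population SD).

    A constant profile (SD = 0) yields all-zero z-scores with a warning.
    """
    mu = p.counts.mean() if len(p.counts) else 0.0
    sd = p.counts.std() if len(p.counts) else 0.0
    if sd == 0:
        logger.warning("standardize_profile: zero SD, returning zeros")
        return np.zeros_like(p.counts)
    return (p.counts - mu) / sd


def detect_duplication(
    carrier: DepthProfile,
    reference: DepthProfile,
    min_windows: int = 4,
    z_threshold: float = 2.0,
) -> list[DuplicationCall]:
    """Call duplication-like intervals from a carrier-vs-reference scan.

    Windows where carrier z minus reference z is at least ``z_threshold``
    are grouped into maximal runs; runs of at least ``min_windows``
    windows are reported. The fold change over a run compares the two
    groups' counts after normalising each profile by its own regional
    mean, so cohort-level depth differences do not mimic CNVs.
    """
    if len(carrier.starts) != len(reference.starts) or carrier.window != reference.window:
        raise ValueError("carrier and reference profiles must share windows")
    zc = standardize_profile(carrier)
    zr = standardize_profile(reference)
    hot = (zc - zr) >= z_threshold
    calls: list[DuplicationCall] = []
    c_norm = carrier.counts / max(carrier.counts.mean(), 1e-12)
    r_norm = reference.counts / max(reference.counts.mean(), 1e-12)
    i = 0
    n = len(hot)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        if j - i + 1 >= min_windows:
            num = c_norm[i : j + 1].mean()
            den = max(r_norm[i : j + 1].mean(), 1e-12)
            calls.append(
                DuplicationCall(
                    chrom=carrier.chrom,
                    start=int(carrier.starts[i]),
                    end=int(carrier.starts[j]) + carrier.window - 1,
                    n_windows=j - i + 1,
                    fold_change=float(num / den),
                    mean_z_diff=float((zc - zr)[i : j + 1].mean()),
                )
            )
        i = j + 1
    return calls


def deletion_read_support(
    reads: pd.DataFrame, target: tuple[str, int, int], by: str = "ANIMAL"
) -> pd.Series:
    """Count reads that fully span a short target interval, per animal.

    ``reads`` holds aligned read intervals with columns
    ``CHROM, START, END, ANIMAL`` (1-based inclusive). Carriers of a
    deletion/replacement of the target show counts near zero because no
    read alignment can continue across the missing sequence.
    """
    chrom, start, end = target
    sub = reads[
        (reads["CHROM"].astype(str) == str(chrom))
        & (reads["START"] <= start)
        & (reads["END"] >= end)
    ]
    counts = sub.groupby(by).size()
    # animals present in the input but with no spanning read get 0
    all_animals = reads[by].unique()
    return counts.reindex(all_animals, fill_value=0).astype(int)


def calls_to_bed(calls: list[DuplicationCall]) -> pd.DataFrame:
    """Duplication calls as BED (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "start": [c.start - 1 for c in calls],
            "end": [c.end for c in calls],
            "name": [f"dup_fold_{c.fold_change:.2f}" for c in calls],
            "score": [c.mean_z_diff for c in calls],
        }
    )
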