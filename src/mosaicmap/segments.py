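"""Window-origin classification, segment calling and length spectra.

A window is assigned to the population against which the individual's
windowed differentiation is lower; maximal runs of same-origin windows
form introgressed segments. Comparing the real segment-length spectrum
with a neutral breed-formation simulation asks whether segments as long
as the observed ones arise without selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestry import WindowStatTable

TAURINE = "taurine"
INDICINE = "indicine"
NO_CALL = "no_call"


def classify_windows(stats: WindowStatTable) -> pd.DataFrame:
    """Label each animal × window taurine / indicine / no_call.

    Taurine when the taurine-side average is strictly lower, indicine
    when strictly greater; no_call when either side is non-callable or
    the two averages tie exactly.
    """
    w = stats.windows.copy()
    ok = w["callable_tau"] & w["callable_ind"]
    label = np.full(len(w), NO_CALL, dtype=object)
    tau = ok & (w["bosind_tau"] < w["bosind_ind"])
    ind = ok & (w["bosind_tau"] > w["bosind_ind"])
    label[tau.to_numpy()] = TAURINE
    label[ind.to_numpy()] = INDICINE
    w["label"] = label
    return w[["animal", "chrom", "win_index", "start", "end", "label"]]


def call_segments(labels: pd.DataFrame, window: int = 250_000) -> pd.DataFrame:
    """Maximal runs of identical origin per animal and chromosome.

    no_call windows break runs and belong to no segment; runs never
    bridge chromosome boundaries. Window gaps (indices absent from the
    input, e.g. SNP deserts) also break runs.

    Returns one row per segment: animal, chrom, start_win, end_win,
    origin, n_windows, start (bp), end (bp).
    """
    rows = []
    for (animal, chrom), grp in labels.groupby(["animal", "chrom"], sort=True):
        grp = grp.sort_values("win_index")
        run_origin = None
        run_start = run_end = None
        prev_idx = None

        def flush():
            if run_origin in (TAURINE, INDICINE):
                rows.append(
                    (
                        animal, chrom, run_start, run_end, run_origin,
                        run_end - run_start + 1,
                        run_start * window + 1,
                        (run_end + 1) * window,
                    )
                )

        for idx, lab in zip(grp["win_index"], grp["label"]):
            contiguous = prev_idx is not None and idx == prev_idx + 1
            if lab == run_origin and contiguous:
                run_end = idx
            else:
                flush()
                run_origin, run_start, run_end = lab, idx, idx
            prev_idx = idx
        flush()
    return pd.DataFrame(
        rows,
        columns=[
            "animal", "chrom", "start_win", "end_win", "origin",
            "n_windows", "start", "end",
        ],
    )


def length_spectrum(segments: pd.DataFrame, origin: str) -> pd.DataFrame:
    """Histogram of segment lengths (in windows), pooled over animals.

    Returns columns ``n_windows, count, fraction``; fractions sum to 1
    (empty input gives an empty spectrum).
    """
    sub = segments[segments["origin"] == origin]
    if sub.empty:
        return pd.DataFrame(columns=["n_windows", "count", "fraction"])
    counts = sub["n_windows"].value_counts().sort_index()
    out = counts.rename("count").reset_index()
    out.columns = ["n_windows", "count"]
    out["fraction"] = out["count"] / out["count"].sum()
    return out


def compare_spectra(real: pd.DataFrame, simulated: pd.DataFrame) -> dict:
    """Compare a real vs a simulated segment-length spectrum.

    Reports the maximum observed length in each dataset and the
    exceedance fraction: the fraction of simulated segments at least as
    long as the longest real segment. An exceedance of 0 says no neutral
    simulated segment reached the observed length.
    """
    real_max = int(real["n_windows"].max()) if len(real) else 0
    sim_max = int(simulated["n_windows"].max()) if len(simulated) else 0
    if len(simulated) and real_max > 0:
        tail = simulated.loc[simulated["n_windows"] >= real_max, "count"].sum()
        exceedance = float(tail / simulated["count"].sum())
    else:
        exceedance = float("nan") if real_max == 0 else 0.0
    table = (
        real.rename(columns={"count": "count_real", "fraction": "fraction_real"})
        .merge(
            simulated.rename(
                columns={"count": "count_sim", "fraction": "fraction_sim"}
            ),
            on="n_windows",
            how="outer",
        )
        .fillna(0)
        .sort_values("n_windows")
        .reset_index(drop=True)
    )
    return {
        "real_max_windows": real_max,
        "simulated_max_windows": sim_max,
        "exceedance_fraction": exceedance,
        "table": table,
    }


def segments_to_bed(segments: pd.DataFrame) -> pd.DataFrame:
    """Segments as BED (0-based half-open), one row per segment."""
    return pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"] - 1,
            "end": segments["end"],
            "name": segments["animal"] + ":" + segments["origin"],
            "score": segments["n_windows"],
        }
    )
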