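"""Non-overlapping window averaging and empirical outlier calling.

Per-SNP statistics (|iHS| or posterior-mean F_ST) are averaged over
non-overlapping 500-kb windows; windows in the extreme upper tail of the
empirical distribution of window means (5% for |iHS|, 2.5% for F_ST by
convention here) are flagged as candidate selection signals, and windows
flagged by both statistics are reported side by side.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WINDOW_BP = 500_000


def window_average(snp_table: pd.DataFrame, stat: str,
                   window_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Average ``stat`` over non-overlapping windows of ``window_bp``.

    Window index is ``floor((pos - 1) / window_bp)`` (1-based positions), so
    position ``window_bp`` still belongs to window 0.  Windows containing no
    SNP are omitted, not zero-filled.
    """
    df = snp_table.dropna(subset=[stat])
    if df.empty:
        raise ValueError("no finite statistics to average")
    win = (df["pos"].to_numpy() - 1) // window_bp
    grouped = (df.assign(window=win)
                 .groupby(["chrom", "window"], sort=True, observed=True)[stat]
                 .agg(mean_stat="mean", n_snp="size")
                 .reset_index())
    grouped["start"] = grouped["window"] * window_bp + 1
    grouped["end"] = (grouped["window"] + 1) * window_bp
    grouped["stat_name"] = stat
    out = grouped[["chrom", "window", "start", "end", "n_snp",
                   "mean_stat", "stat_name"]]
    out.attrs["window_bp"] = window_bp
    return out


def empirical_threshold(windows: pd.DataFrame,
                        upper_q: float,
                        lower_tail: bool = False) -> tuple[float, pd.DataFrame]:
    """Flag windows beyond the empirical ``upper_q`` tail of the mean statistic.

    The threshold is the linear-interpolation ``1 - upper_q`` quantile of the
    window means; flagging is strict (``>``), so when all values tie with the
    threshold nothing is flagged.  ``lower_tail=True`` flags the symmetric
    lower tail instead (balancing-selection convention; off by default).
    """
    if not 0 < upper_q < 1:
        raise ValueError("upper_q must be in (0, 1)")
    vals = windows["mean_stat"].to_numpy()
    if vals.size < 1 / upper_q:
        warnings.warn(f"only {vals.size} windows for a {upper_q:.3f} tail; "
                      "threshold is noisy")
    if lower_tail:
        thr = float(np.quantile(vals, upper_q))
        flagged = windows.assign(significant=vals < thr)
    else:
        thr = float(np.quantile(vals, 1 - upper_q))
        flagged = windows.assign(significant=vals > thr)
    flagged.attrs.update(windows.attrs)
    return thr, flagged


def overlap_signals(ihs_windows: pd.DataFrame,
                    fst_windows: pd.DataFrame) -> pd.DataFrame:
    """Windows significant under both statistics, side by side
    (chrom, start, end, fst mean, |iHS| mean)."""
    wa = ihs_windows.attrs.get("window_bp")
    wb = fst_windows.attrs.get("window_bp")
    if wa is not None and wb is not None and wa != wb:
        raise ValueError(f"mismatched window sizes: {wa} vs {wb}")
    a = ihs_windows[ihs_windows["significant"]]
    b = fst_windows[fst_windows["significant"]]
    merged = a.merge(b, on=["chrom", "window", "start", "end"],
                     suffixes=("_ihs", "_fst"))
    out = merged[["chrom", "window", "start", "end",
                  "mean_stat_fst", "mean_stat_ihs",
                  "n_snp_ihs", "n_snp_fst"]].rename(
        columns={"mean_stat_fst": "fst", "mean_stat_ihs": "abs_ihs"})
    return out.sort_values(["chrom", "window"]).reset_index(drop=True)


def windows_to_bed(windows: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """0-based half-open BED view of (significant) windows."""
    df = windows[windows["significant"]] if significant_only else windows
    return pd.DataFrame({"chrom": df["chrom"], "start": df["start"] - 1,
                         "end": df["end"]})
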