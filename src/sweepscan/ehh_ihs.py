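"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

For a core SNP and one of its two alleles, EHH at a target marker is the
probability that two randomly drawn carrier haplotypes are identical over the
closed marker interval from the core to the target:

    EHH = sum_h C(c_h, 2) / C(c, 2)

where the ``c`` carriers split into groups of identical sub-haplotypes of
sizes ``c_h``.  EHH is 1 at the core and non-increasing outward (widening the
interval only refines the grouping).

iHH is the area under the EHH-versus-distance curve on each side of the core,
truncated by linear interpolation at the position where EHH crosses the floor
(0.05 by default), summed over both sides.  The unstandardized score is
``ln(iHH_A / iHH_D)`` (ancestral over derived core allele); scores are then
standardized to mean 0, variance 1 within derived-allele-frequency bins so
that extreme |iHS| is comparable across frequencies.

Distances are physical (bp).  The log-ratio is invariant under any global
rescaling of positions, so no genetic map is required.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .panel import ANCESTRAL_UNKNOWN, MISSING, HaplotypePanel

EHH_FLOOR = 0.05


@dataclasses.dataclass
class EHHCurve:
    """EHH evaluated marker-by-marker outward from a core SNP, one allele."""

    core: int
    allele: str                      # "ancestral" or "derived"
    core_pos: int
    left: list[tuple[int, float]]    # (pos, EHH) outward; excludes the core point
    right: list[tuple[int, float]]
    left_reached: bool               # EHH fell below the floor before the chrom end
    right_reached: bool
    n_carriers: int


def _carrier_rows(panel: HaplotypePanel, core: int, allele: str) -> np.ndarray:
    anc = int(panel.variants["ancestral"].iloc[core])
    if anc == ANCESTRAL_UNKNOWN:
        raise ValueError(f"ancestral allele unknown at variant {core}")
    if allele == "ancestral":
        code = anc
    elif allele == "derived":
        code = 1 - anc
    else:
        raise ValueError(f"allele must be 'ancestral' or 'derived', got {allele!r}")
    return np.flatnonzero(panel.haplotypes[:, core] == code)


def _homozygosity(groups: np.ndarray) -> float:
    counts = np.bincount(groups)
    c = groups.size
    return float((counts * (counts - 1)).sum() / (c * (c - 1)))


def ehh_at(panel: HaplotypePanel, core: int, allele: str, target: int) -> float:
    """EHH among core-allele carriers over the closed interval [core, target]."""
    if panel.variants["chrom"].iloc[core] != panel.variants["chrom"].iloc[target]:
        raise ValueError("core and target must share a chromosome")
    rows = _carrier_rows(panel, core, allele)
    if rows.size < 2:
        raise ValueError("EHH undefined: fewer than 2 carrier haplotypes")
    lo, hi = min(core, target), max(core, target)
    block = panel.haplotypes[np.ix_(rows, np.arange(lo, hi + 1))]
    _, groups = np.unique(block, axis=0, return_inverse=True)
    return _homozygosity(groups)


def _walk_side(H: np.ndarray, rows: np.ndarray, cols: np.ndarray,
               pos: np.ndarray, ehh_floor: float) -> tuple[list, bool]:
    """Refine carrier grouping marker-by-marker along ``cols``; stop at the
    first marker where EHH < floor (kept as the crossing anchor)."""
    groups = np.zeros(rows.size, dtype=np.int64)
    points: list[tuple[int, float]] = []
    for j in cols:
        key = groups * 2 + H[rows, j]
        _, groups = np.unique(key, return_inverse=True)
        e = _homozygosity(groups)
        points.append((int(pos[j]), e))
        if e < ehh_floor:
            return points, True
    return points, False


def ehh_curve(panel: HaplotypePanel, core: int, allele: str,
              ehh_floor: float = EHH_FLOOR) -> EHHCurve:
    """EHH curve for one core allele, evaluated outward on both sides."""
    rows = _carrier_rows(panel, core, allele)
    if rows.size < 2:
        raise ValueError("EHH undefined: fewer than 2 carrier haplotypes")
    chrom = panel.variants["chrom"].iloc[core]
    on_chrom = np.flatnonzero((panel.variants["chrom"] == chrom).to_numpy())
    pos = panel.variants["pos"].to_numpy()
    H = panel.haplotypes
    left_cols = on_chrom[on_chrom < core][::-1]
    right_cols = on_chrom[on_chrom > core]
    left, l_reached = _walk_side(H, rows, left_cols, pos, ehh_floor)
    right, r_reached = _walk_side(H, rows, right_cols, pos, ehh_floor)
    return EHHCurve(core=core, allele=allele, core_pos=int(pos[core]),
                    left=left, right=right,
                    left_reached=l_reached, right_reached=r_reached,
                    n_carriers=int(rows.size))


def _side_area(core_pos: int, points: list[tuple[int, float]],
               reached: bool, ehh_floor: float, truncation: str) -> tuple[float, bool]:
    """Trapezoidal area of one side from the core to the interpolated floor
    crossing; returns (area, valid)."""
    offs = [0.0] + [abs(p - core_pos) for p, _ in points]
    vals = [1.0] + [v for _, v in points]
    area = 0.0
    for (o0, v0), (o1, v1) in zip(zip(offs, vals), zip(offs[1:], vals[1:])):
        if v1 >= ehh_floor:
            area += 0.5 * (v0 + v1) * (o1 - o0)
        else:
            frac = (v0 - ehh_floor) / (v0 - v1)
            o_cross = o0 + frac * (o1 - o0)
            area += 0.5 * (v0 + ehh_floor) * (o_cross - o0)
            return area, True
    if reached:  # defensive; the loop above should have returned
        return area, True
    return area, truncation == "truncate"


def ihh(curve: EHHCurve, ehh_floor: float = EHH_FLOOR,
        truncation: str = "exclude") -> tuple[float, bool]:
    """Integrated EHH over both sides of the core.

    Returns ``(area, valid)``; ``valid`` is False when a side never reached
    the floor before the chromosome end under the default ``"exclude"``
    truncation policy.
    """
    if truncation not in ("exclude", "truncate"):
        raise ValueError(f"unknown truncation policy {truncation!r}")
    la, lv = _side_area(curve.core_pos, curve.left, curve.left_reached,
                        ehh_floor, truncation)
    ra, rv = _side_area(curve.core_pos, curve.right, curve.right_reached,
                        ehh_floor, truncation)
    return la + ra, lv and rv


def ihs_raw(ihh_a: float, ihh_d: float) -> float:
    """Unstandardized score ln(iHH_A / iHH_D); antisymmetric in its arguments."""
    if ihh_a <= 0 or ihh_d <= 0:
        raise ValueError("iHH areas must be positive")
    return float(np.log(ihh_a / ihh_d))


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------

def _merge_small_bins(bins: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Merge under-filled frequency bins into their nearest occupied neighbor.

    Returns a relabelling of ``bins`` into merged group ids."""
    group_of = np.arange(n_bins)

    def counts_by_group():
        g = group_of[bins]
        return {k: int(v) for k, v in zip(*np.unique(g, return_counts=True))}

    while True:
        cnt = counts_by_group()
        small = [g for g, c in sorted(cnt.items()) if c < min_count]
        if not small or len(cnt) == 1:
            break
        g = small[0]
        others = [h for h in cnt if h != g]
        # nearest occupied group by distance between member bin indices
        members = np.flatnonzero(group_of == g)
        nearest = min(others,
                      key=lambda h: np.abs(np.subtract.outer(
                          members, np.flatnonzero(group_of == h))).min())
        group_of[group_of == g] = nearest
    return group_of[bins]


def standardize_ihs(records: pd.DataFrame, n_bins: int = 20,
                    min_bin_count: int = 10) -> pd.DataFrame:
    """Standardize raw scores to mean 0, variance 1 (n-1 denominator) within
    derived-allele-frequency bins.

    ``records`` needs columns ``derived_freq``, ``ihs_raw``, ``valid``.
    Invalid records are excluded from bin statistics and left unstandardized.
    """
    out = records.copy()
    out["ihs_std"] = np.nan
    out["abs_ihs"] = np.nan
    out["freq_bin"] = -1
    valid = out["valid"].to_numpy().astype(bool)
    if valid.sum() == 0:
        return out
    freq = out.loc[valid, "derived_freq"].to_numpy()
    raw = out.loc[valid, "ihs_raw"].to_numpy()
    bins = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
    merged = _merge_small_bins(bins, n_bins, min_bin_count)
    if len(np.unique(merged)) == 1 and valid.sum() == 1:
        raise ValueError("cannot standardize a single record")

    std = np.full(raw.shape, np.nan)
    still_valid = np.ones(raw.shape, dtype=bool)
    for g in np.unique(merged):
        sel = merged == g
        if sel.sum() < 2:
            still_valid[sel] = False
            continue
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=1)
        if sd == 0:
            still_valid[sel] = False
            continue
        std[sel] = (raw[sel] - mu) / sd

    vidx = np.flatnonzero(valid)
    out.loc[out.index[vidx], "ihs_std"] = std
    out.loc[out.index[vidx], "abs_ihs"] = np.abs(std)
    out.loc[out.index[vidx], "freq_bin"] = merged
    dropped = vidx[~still_valid]
    out.loc[out.index[dropped], "valid"] = False
    out.loc[out.index[dropped], "reason"] = "degenerate_bin"
    out.loc[out.index[dropped], ["ihs_std", "abs_ihs"]] = np.nan
    out.loc[out.index[dropped], "freq_bin"] = -1
    return out


# ----------------------------------------------------------------------
# genome scan
# ----------------------------------------------------------------------

def ihs_scan(panel: HaplotypePanel, ehh_floor: float = EHH_FLOOR,
             truncation: str = "exclude", n_bins: int = 20,
             min_bin_count: int = 10,
             max_gap_bp: int | None = None) -> pd.DataFrame:
    """Per-SNP |iHS| over the whole panel.

    Returns a tidy table keyed by (chrom, pos) with columns ``derived_freq,
    iHH_A, iHH_D, ihs_raw, ihs_std, abs_ihs, valid, reason, freq_bin``.
    Chromosomes with fewer than 3 SNPs are skipped with a warning.
    """
    if np.any(panel.haplotypes == MISSING):
        raise ValueError("iHS scan requires fully called (phased) haplotypes")
    rows = []
    pos_all = panel.variants["pos"].to_numpy()
    anc_all = panel.variants["ancestral"].to_numpy()
    dfreq = panel.derived_freq()
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 3:
            warnings.warn(f"chromosome {chrom} has < 3 SNPs; skipped")
            continue
        gap_bad = np.zeros(idx.size, dtype=bool)
        if max_gap_bp is not None:
            gaps = np.diff(pos_all[idx])
            big = gaps > max_gap_bp
            gap_bad[:-1] |= big
            gap_bad[1:] |= big
        for local, core in enumerate(idx):
            rec = {"chrom": chrom, "pos": int(pos_all[core]),
                   "derived_freq": float(dfreq[core]),
                   "iHH_A": np.nan, "iHH_D": np.nan, "ihs_raw": np.nan,
                   "valid": False, "reason": ""}
            if anc_all[core] == ANCESTRAL_UNKNOWN:
                rec["reason"] = "no_ancestral"
                rows.append(rec)
                continue
            if gap_bad[local]:
                rec["reason"] = "gap"
                rows.append(rec)
                continue
            n_d = int(round(rec["derived_freq"] * panel.n_haplotypes))
            if n_d < 2 or panel.n_haplotypes - n_d < 2:
                rec["reason"] = "few_carriers"
                rows.append(rec)
                continue
            area = {}
            ok = True
            for allele, key in (("ancestral", "iHH_A"), ("derived", "iHH_D")):
                curve = ehh_curve(panel, core, allele, ehh_floor)
                a, v = ihh(curve, ehh_floor, truncation)
                area[key] = a
                ok = ok and v
            rec["iHH_A"], rec["iHH_D"] = area["iHH_A"], area["iHH_D"]
            if not ok:
                rec["reason"] = "edge"
            elif area["iHH_A"] <= 0 or area["iHH_D"] <= 0:
                rec["reason"] = "zero_area"
            else:
                rec["ihs_raw"] = ihs_raw(area["iHH_A"], area["iHH_D"])
                rec["valid"] = True
            rows.append(rec)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no scannable chromosomes")
    return standardize_ihs(table, n_bins=n_bins, min_bin_count=min_bin_count)


def split_half_validation(panel: HaplotypePanel, seed: int,
                          split: tuple[np.ndarray, np.ndarray] | None = None,
                          **scan_kwargs) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Cross-validation of the scan: split individuals in two, scan each half,
    and correlate |iHS| over SNPs valid in both halves."""
    if split is None:
        if panel.n_samples < 20:
            raise ValueError("need >= 20 diploid individuals to split")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(panel.n_samples)
        split = (np.sort(perm[: panel.n_samples // 2]),
                 np.sort(perm[panel.n_samples // 2:]))
    s1 = ihs_scan(panel.take_samples(split[0]), **scan_kwargs)
    s2 = ihs_scan(panel.take_samples(split[1]), **scan_kwargs)
    merged = s1.merge(s2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    both = merged["valid_1"].astype(bool) & merged["valid_2"].astype(bool)
    if both.sum() < 3:
        raise ValueError("too few SNPs valid in both halves")
    r = stats.pearsonr(merged.loc[both, "abs_ihs_1"],
                       merged.loc[both, "abs_ihs_2"]).statistic
    return s1, s2, float(r)
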