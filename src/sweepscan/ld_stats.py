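"""Linkage-disequilibrium and marker summaries.

r² is computed from phased haplotype columns (not genotype correlation):
``r² = D² / (p_i(1-p_i) p_j(1-p_j))`` with ``D = p_ij - p_i p_j``.  The decay
table averages r² over intra-chromosomal SNP pairs binned by physical
distance; marker summaries report MAF, observed heterozygosity and
inter-marker spacing in the units usual for chip panels (kb).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

#: default decay bins: 50-kb width out to 5 Mb
DEFAULT_BIN_EDGES = np.arange(0, 5_000_001, 50_000)


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared haplotype-frequency correlation between variants ``i`` and ``j``.

    Raises ``ValueError`` for monomorphic variants (r² undefined).
    """
    if i == j:
        raise ValueError("i and j must differ")
    a = panel.haplotypes[:, i].astype(float)
    b = panel.haplotypes[:, j].astype(float)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    p_i, p_j = a.mean(), b.mean()
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise ValueError("undefined r2: monomorphic variant")
    D = (a * b).mean() - p_i * p_j
    return float(D * D / (p_i * (1 - p_i) * p_j * (1 - p_j)))


def _r2_matrix_block(H: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (n_hap, n_snp) 0/1 block; NaN where undefined."""
    p = H.mean(axis=0)
    var = p * (1 - p)
    c = H.T @ H / H.shape[0] - np.outer(p, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = c * c / np.outer(var, var)
    r2[var == 0, :] = np.nan
    r2[:, var == 0] = np.nan
    return r2


def ld_decay(panel: HaplotypePanel,
             bin_edges: np.ndarray = DEFAULT_BIN_EDGES,
             max_dist: int | None = None) -> pd.DataFrame:
    """Mean r² by inter-marker distance bin over all intra-chromosomal pairs.

    Pairs involving monomorphic SNPs are skipped (and tallied in the
    ``skipped`` attribute of the returned frame).  Empty bins report
    ``n_pairs = 0`` and NaN mean.
    """
    bin_edges = np.asarray(bin_edges)
    if max_dist is None:
        max_dist = int(bin_edges[-1])
    sums = np.zeros(len(bin_edges) - 1)
    counts = np.zeros(len(bin_edges) - 1, dtype=np.int64)
    skipped = 0
    for _, grp in panel.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            continue
        pos = grp["pos"].to_numpy()
        r2 = _r2_matrix_block(panel.haplotypes[:, idx].astype(float))
        iu, ju = np.triu_indices(idx.size, k=1)
        d = pos[ju] - pos[iu]
        within = d <= max_dist
        vals = r2[iu[within], ju[within]]
        d = d[within]
        bad = np.isnan(vals)
        skipped += int(bad.sum())
        vals, d = vals[~bad], d[~bad]
        which = np.digitize(d, bin_edges) - 1
        ok = (which >= 0) & (which < len(sums))
        np.add.at(sums, which[ok], vals[ok])
        np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"bin_lo": bin_edges[:-1], "bin_hi": bin_edges[1:],
                        "mean_r2": mean, "n_pairs": counts})
    out.attrs["skipped_monomorphic_pairs"] = skipped
    return out


@dataclasses.dataclass
class MarkerSummary:
    n_snp: int
    maf_mean: float
    maf_sd: float
    obs_het_mean: float
    obs_het_sd: float
    intermarker_mean_kb: float
    intermarker_sd_kb: float
    max_gap_kb: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def marker_summary(panel: HaplotypePanel) -> MarkerSummary:
    """Table-1-style panel summary: MAF, observed heterozygosity, spacing."""
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    maf = panel.maf()
    H = panel.haplotypes
    a, b = H[0::2], H[1::2]
    called = (a != MISSING) & (b != MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(called.sum(axis=0) > 0,
                       ((a != b) & called).sum(axis=0)
                       / np.maximum(called.sum(axis=0), 1), np.nan)
    gaps = [np.diff(g["pos"].to_numpy())
            for _, g in panel.variants.groupby("chrom", sort=False)
            if len(g) >= 2]
    gaps = np.concatenate(gaps) if gaps else np.array([])
    return MarkerSummary(
        n_snp=panel.n_variants,
        maf_mean=float(np.nanmean(maf)),
        maf_sd=(float(np.nanstd(maf, ddof=1))
                if np.count_nonzero(~np.isnan(maf)) > 1 else float("nan")),
        obs_het_mean=float(np.nanmean(het)),
        obs_het_sd=(float(np.nanstd(het, ddof=1))
                    if np.count_nonzero(~np.isnan(het)) > 1 else float("nan")),
        intermarker_mean_kb=float(gaps.mean() / 1e3) if gaps.size else float("nan"),
        intermarker_sd_kb=float(gaps.std(ddof=1) / 1e3) if gaps.size > 1 else float("nan"),
        max_gap_kb=float(gaps.max() / 1e3) if gaps.size else float("nan"),
    )


def plot_ld_decay(decay: pd.DataFrame, path: str) -> None:
    """Diagnostic plot of mean r² against distance (kb)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mid = (decay["bin_lo"] + decay["bin_hi"]) / 2e3
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(mid, decay["mean_r2"], "o-", ms=3)
    ax.set_xlabel("inter-marker distance (kb)")
    ax.set_ylabel("mean $r^2$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
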