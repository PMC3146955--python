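"""Gene-content enrichment of significant windows.

Each significant window is represented by its midpoint; the number of
annotated genes overlapping the 1-Mb bracket centered there classifies the
region as gene-poor (count <= ``poor_max_genes``) or not.  The same
classification is applied to random positions sampled uniformly per
chromosome with the same per-chromosome counts as the significant windows,
and the observed-vs-random contrast is tested with a Pearson chi-square on
the 2x2 table (1 df, no continuity correction).

There is no universal numeric cutoff for "poor gene content"; the threshold
is a required, explicit parameter of the test.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

BRACKET_BP = 1_000_000


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3/BED4+ gene annotation (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = [f"g{i}" for i in range(len(df))]
    if (df["start"] >= df["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def gene_count_in_bracket(genes: pd.DataFrame, chrom: str, midpoint: int,
                          bracket_bp: int = BRACKET_BP,
                          chrom_length: int | None = None) -> int:
    """Genes overlapping the bracket of ``bracket_bp`` centered on ``midpoint``
    (clipped at the chromosome bounds); partial overlap counts."""
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        if chrom not in set(genes["chrom"]):
            warnings.warn(f"chromosome {chrom!r} absent from the annotation")
        return 0
    lo = max(0, midpoint - bracket_bp // 2)
    hi = midpoint + bracket_bp // 2
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return int(((sub["start"] < hi) & (sub["end"] > lo)).sum())


def sample_matched_positions(sig_windows: pd.DataFrame,
                             chrom_lengths: dict[str, int],
                             seed: int) -> pd.DataFrame:
    """Uniform random positions matching the per-chromosome counts of the
    significant windows exactly."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in sig_windows.groupby("chrom", sort=True):
        if chrom not in chrom_lengths:
            raise ValueError(f"no length known for chromosome {chrom!r}")
        pos = rng.integers(1, chrom_lengths[chrom] + 1, size=len(grp))
        rows += [(chrom, int(p)) for p in np.sort(pos)]
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the table
    [[a, b], [c, d]]; returns (statistic, p-value)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass
class EnrichmentResult:
    a: int   # observed windows in gene-poor regions
    b: int   # observed windows elsewhere
    c: int   # random positions in gene-poor regions
    d: int   # random positions elsewhere
    chi2: float
    p_value: float
    poor_max_genes: int
    significant_at: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.significant_at

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


def enrichment_test(sig_windows: pd.DataFrame, genes: pd.DataFrame,
                    chrom_lengths: dict[str, int], poor_max_genes: int,
                    seed: int, bracket_bp: int = BRACKET_BP) -> EnrichmentResult:
    """Test whether significant windows fall in gene-poor regions more often
    than chromosome-matched random positions do."""
    if len(sig_windows) == 0:
        raise ValueError("empty table: no significant windows to test")
    mid = ((sig_windows["start"] + sig_windows["end"]) // 2).to_numpy()
    obs_counts = [gene_count_in_bracket(genes, ch, int(m), bracket_bp,
                                        chrom_lengths.get(ch))
                  for ch, m in zip(sig_windows["chrom"], mid)]
    rand = sample_matched_positions(sig_windows, chrom_lengths, seed)
    rand_counts = [gene_count_in_bracket(genes, ch, int(p), bracket_bp,
                                         chrom_lengths.get(ch))
                   for ch, p in zip(rand["chrom"], rand["pos"])]
    a = int(sum(c <= poor_max_genes for c in obs_counts))
    b = len(obs_counts) - a
    c = int(sum(cc <= poor_max_genes for cc in rand_counts))
    d = len(rand_counts) - c
    chi2, p = chi2_2x2(a, b, c, d)
    return EnrichmentResult(a=a, b=b, c=c, d=d, chi2=chi2, p_value=p,
                            poor_max_genes=poor_max_genes)
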