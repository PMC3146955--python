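"""Core in-memory container for phased SNP panels.

A :class:`HaplotypePanel` holds a phased 0/1 haplotype matrix together with the
variant map (chromosome, 1-based position, ancestral-allele annotation) and the
sample sheet (sample ID, population label).  Haplotype rows come in pairs: rows
``2i`` and ``2i + 1`` are the two phased haplotypes of diploid sample ``i``.

Allele codes are the file codes (0 = first/REF allele, 1 = second/ALT allele,
``MISSING`` = -1 for a missing call, permitted only pre-phasing).  Which allele
is ancestral at each site is recorded per variant in ``variants['ancestral']``
(0, 1, or ``ANCESTRAL_UNKNOWN`` = -1); haplotype-based statistics polarize with
that column rather than assuming the matrix itself is polarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
ANCESTRAL_UNKNOWN = -1

#: chromosome labels dropped at read time (autosome-only analyses)
NON_AUTOSOMAL = {"x", "y", "mt", "chrx", "chry", "chrmt", "chrm"}

VARIANT_COLUMNS = ["id", "chrom", "pos", "ancestral", "placed"]
SAMPLE_COLUMNS = ["sample_id", "population"]


class PanelError(ValueError):
    """Raised when panel data violate the container invariants."""


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix plus variant map and sample sheet.

    Parameters
    ----------
    haplotypes
        int8 matrix of shape ``(2 * n_samples, n_variants)`` with entries in
        {0, 1, MISSING}.
    variants
        DataFrame with columns ``id, chrom, pos, ancestral, placed`` sorted by
        ``(chrom, pos)``; positions are 1-based and strictly increasing within
        a chromosome.
    samples
        DataFrame with columns ``sample_id, population``.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.haplotypes.ndim != 2:
            raise PanelError("haplotype matrix must be 2-D")
        n_hap, n_var = self.haplotypes.shape
        if n_hap != 2 * len(self.samples):
            raise PanelError(
                f"haplotype rows ({n_hap}) != 2 x samples ({len(self.samples)})"
            )
        if n_var != len(self.variants):
            raise PanelError(
                f"haplotype columns ({n_var}) != variants ({len(self.variants)})"
            )
        codes = np.unique(self.haplotypes)
        bad = set(codes.tolist()) - {0, 1, MISSING}
        if bad:
            raise PanelError(f"illegal allele codes {sorted(bad)}")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise PanelError(f"variant table lacks columns {missing_cols}")
        if (self.variants["pos"] < 1).any():
            raise PanelError("variant positions must be >= 1")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise PanelError(f"positions not strictly increasing on {chrom}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.samples["population"]))

    def haplotype_rows_of(self, population: str | None = None) -> np.ndarray:
        """Row indices of the haplotypes belonging to ``population`` (all if None)."""
        if population is None:
            idx = np.arange(self.n_samples)
        else:
            idx = np.flatnonzero(self.samples["population"].to_numpy() == population)
        return np.stack([2 * idx, 2 * idx + 1], axis=1).reshape(-1)

    def take_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        """Sub-panel restricted to the given sample indices (order kept)."""
        sample_idx = np.asarray(sample_idx, dtype=int)
        rows = np.stack([2 * sample_idx, 2 * sample_idx + 1], axis=1).reshape(-1)
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows].copy(),
            variants=self.variants.copy(),
            samples=self.samples.iloc[sample_idx].copy(),
        )

    def take_variants(self, variant_idx: np.ndarray) -> "HaplotypePanel":
        """Sub-panel restricted to the given variant indices (order kept)."""
        variant_idx = np.asarray(variant_idx, dtype=int)
        return HaplotypePanel(
            haplotypes=self.haplotypes[:, variant_idx].copy(),
            variants=self.variants.iloc[variant_idx].copy(),
            samples=self.samples.copy(),
        )

    # ------------------------------------------------------------------
    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Frequency of allele 1 per variant, over non-missing calls in ``rows``."""
        H = self.haplotypes if rows is None else self.haplotypes[rows]
        called = H != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, (H == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        return p

    def maf(self, rows: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(rows)
        return np.minimum(p, 1.0 - p)

    def derived_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Derived-allele frequency per variant; NaN where ancestral is unknown."""
        p1 = self.allele_freq(rows)
        anc = self.variants["ancestral"].to_numpy()
        out = np.where(anc == 0, p1, np.where(anc == 1, 1.0 - p1, np.nan))
        return out

    def equal(self, other: "HaplotypePanel") -> bool:
        return (
            np.array_equal(self.haplotypes, other.haplotypes)
            and self.variants[VARIANT_COLUMNS].equals(other.variants[VARIANT_COLUMNS])
            and self.samples[SAMPLE_COLUMNS].equals(other.samples[SAMPLE_COLUMNS])
        )


def make_variant_table(
    ids, chroms, pos, ancestral=None, placed=None
) -> pd.DataFrame:
    n = len(pos)
    if ancestral is None:
        ancestral = np.full(n, ANCESTRAL_UNKNOWN)
    if placed is None:
        placed = np.ones(n, dtype=bool)
    return pd.DataFrame(
        {
            "id": list(ids),
            "chrom": list(chroms),
            "pos": np.asarray(pos, dtype=np.int64),
            "ancestral": np.asarray(ancestral, dtype=np.int8),
            "placed": np.asarray(placed, dtype=bool),
        }
    )
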