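"""Panel input/output and quality control.

Two on-disk formats are supported:

* phased VCF (``GT`` with ``|`` separators; optional ``INFO/AA`` carries the
  ancestral allele), read through :mod:`cyvcf2`;
* ``hap_tsv`` — a deterministic, diff-able plain-text dialect: a header row
  ``id  chrom  pos  ancestral  <hap column names>``, then one row per variant
  with one ``0``/``1``/``.`` code per haplotype column.  Haplotype columns are
  named ``<sample>_a`` / ``<sample>_b``.

Population labels live in a separate two-column popmap TSV
(``sample_id<TAB>population``).

Quality control produces one of two analysis datasets:

* ``LD_dataset`` — for LD and haplotype statistics: drops high-missingness
  samples, unplaced variants, variants without a known ancestral allele, and
  variants with pooled MAF below the floor;
* ``FST_dataset`` — for the site-frequency analysis: keeps low-MAF and
  monomorphic loci (only high-missingness samples and unplaced variants go).

Non-autosomal chromosomes (X, Y, MT) are dropped at read time.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (
    ANCESTRAL_UNKNOWN,
    MISSING,
    NON_AUTOSOMAL,
    HaplotypePanel,
    PanelError,
    make_variant_table,
)

LD_DATASET = "LD_dataset"
FST_DATASET = "FST_dataset"

#: fixed charging order: a removed variant is charged to the first matching reason
REASON_ORDER = ("unplaced", "no_ancestral", "low_MAF")


@dataclasses.dataclass
class QCReport:
    """Tally of what quality control removed and why."""

    dataset_tag: str
    samples_removed: list[str]
    variants_removed_by_reason: dict[str, int]

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed)

    def to_frame(self) -> pd.DataFrame:
        rows = [("samples_missingness", self.n_samples_removed)]
        rows += [(f"variants_{r}", c) for r, c in self.variants_removed_by_reason.items()]
        return pd.DataFrame(rows, columns=["reason", "count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# popmap
# ----------------------------------------------------------------------

def read_popmap(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["population"]))


def write_popmap(samples: pd.DataFrame, path: str | Path) -> None:
    samples[["sample_id", "population"]].to_csv(path, sep="\t", index=False,
                                                header=False)


# ----------------------------------------------------------------------
# readers
# ----------------------------------------------------------------------

def read_panel(path: str | Path, format: str, popmap: str | Path) -> HaplotypePanel:
    """Read a phased panel from ``path`` in the given format.

    Parameters
    ----------
    path
        VCF (possibly bgzipped) or hap_tsv file.
    format
        ``"vcf"`` or ``"hap_tsv"``.
    popmap
        Two-column TSV mapping every sample ID to its population.

    Raises
    ------
    PanelError
        On unphased VCF genotypes (naming the record), samples absent from the
        popmap, or duplicated positions on a chromosome.
    """
    pops = read_popmap(popmap)
    if format == "vcf":
        panel = _read_vcf(path, pops)
    elif format == "hap_tsv":
        panel = _read_hap_tsv(path, pops)
    else:
        raise ValueError(f"unknown format {format!r}")
    return panel


def _attach_populations(sample_ids: list[str], pops: dict[str, str]) -> pd.DataFrame:
    absent = [s for s in sample_ids if s not in pops]
    if absent:
        raise PanelError(f"samples missing from popmap: {absent[:5]}")
    return pd.DataFrame({"sample_id": sample_ids,
                         "population": [pops[s] for s in sample_ids]})


def _finalize(haps: np.ndarray, variants: pd.DataFrame,
              samples: pd.DataFrame) -> HaplotypePanel:
    # drop sex chromosomes / MT, sort by (chrom, pos), reject duplicate positions
    keep = ~variants["chrom"].str.lower().isin(NON_AUTOSOMAL)
    variants = variants.loc[keep]
    haps = haps[:, keep.to_numpy()]
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy().astype(str)))
    variants = variants.iloc[order].reset_index(drop=True)
    haps = haps[:, order]
    dup = variants.duplicated(subset=["chrom", "pos"])
    if dup.any():
        r = variants.loc[dup.idxmax()]
        raise PanelError(f"duplicated position {r['chrom']}:{r['pos']}")
    return HaplotypePanel(haplotypes=haps, variants=variants, samples=samples)


def _read_vcf(path: str | Path, pops: dict[str, str]) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    samples = _attach_populations(sample_ids, pops)

    ids, chroms, positions, ancestral = [], [], [], []
    columns = []
    for rec in vcf:
        gts = np.array(rec.genotypes)  # (n_samples, 3): a, b, phased
        miss = gts[:, :2] < 0
        if not bool(np.all(gts[~miss[:, 0], 2])):
            raise PanelError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        col = gts[:, :2].astype(np.int8)
        col[miss] = MISSING
        columns.append(col.reshape(-1))
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        aa = rec.INFO.get("AA")
        if aa is None:
            ancestral.append(ANCESTRAL_UNKNOWN)
        else:
            aa = str(aa)
            if aa == rec.REF:
                ancestral.append(0)
            elif rec.ALT and aa == rec.ALT[0]:
                ancestral.append(1)
            else:
                ancestral.append(ANCESTRAL_UNKNOWN)
    if not columns:
        raise PanelError(f"no variants in {path}")
    haps = np.stack(columns, axis=1)
    variants = make_variant_table(ids, chroms, positions, ancestral)
    return _finalize(haps, variants, samples)


def _read_hap_tsv(path: str | Path, pops: dict[str, str]) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["id", "chrom", "pos", "ancestral"]
    hap_cols = [c for c in df.columns if c not in meta_cols]
    if len(hap_cols) % 2:
        raise PanelError("odd number of haplotype columns")
    sample_ids = []
    for a, b in zip(hap_cols[::2], hap_cols[1::2]):
        if not (a.endswith("_a") and b.endswith("_b") and a[:-2] == b[:-2]):
            raise PanelError(f"haplotype columns not paired: {a}, {b}")
        sample_ids.append(a[:-2])
    samples = _attach_populations(sample_ids, pops)

    codes = df[hap_cols].to_numpy()
    haps = np.where(codes == ".", MISSING, codes).astype(np.int8).T
    anc = df["ancestral"].map({"0": 0, "1": 1, ".": ANCESTRAL_UNKNOWN}).to_numpy()
    variants = make_variant_table(df["id"], df["chrom"],
                                  df["pos"].astype(np.int64), anc)
    return _finalize(haps, variants, samples)


# ----------------------------------------------------------------------
# writers
# ----------------------------------------------------------------------

def write_hap_tsv(panel: HaplotypePanel, path: str | Path) -> None:
    hap_cols = []
    for s in panel.samples["sample_id"]:
        hap_cols += [f"{s}_a", f"{s}_b"]
    codes = panel.haplotypes.T.astype(object)
    codes[codes == MISSING] = "."
    out = pd.DataFrame(codes, columns=hap_cols)
    anc = panel.variants["ancestral"].map({0: "0", 1: "1",
                                           ANCESTRAL_UNKNOWN: "."})
    meta = pd.DataFrame({"id": panel.variants["id"],
                         "chrom": panel.variants["chrom"],
                         "pos": panel.variants["pos"],
                         "ancestral": anc})
    pd.concat([meta, out], axis=1).to_csv(path, sep="\t", index=False)


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (alleles A=code 0, G=code 1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, grp in panel.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1}>\n")
        cols = "\t".join(panel.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        H = panel.haplotypes
        for j, row in panel.variants.iterrows():
            anc = row["ancestral"]
            info = "." if anc == ANCESTRAL_UNKNOWN else f"AA={'A' if anc == 0 else 'G'}"
            gts = []
            for i in range(panel.n_samples):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                gts.append(f"{'.' if a == MISSING else a}|{'.' if b == MISSING else b}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tG\t.\tPASS\t"
                     f"{info}\tGT\t" + "\t".join(gts) + "\n")


# ----------------------------------------------------------------------
# quality control
# ----------------------------------------------------------------------

def qc_filter(
    panel: HaplotypePanel,
    dataset: str,
    max_sample_missing: float = 0.05,
    maf_min: float = 0.05,
) -> tuple[HaplotypePanel, QCReport]:
    """Apply the chip-QC filters and return the requested analysis dataset.

    Samples with a missing-call fraction >= ``max_sample_missing`` are removed
    first (over all variants, before any variant filter).  Unplaced variants go
    in both modes.  For the ``LD_dataset`` only, variants with unknown
    ancestral allele or pooled MAF < ``maf_min`` are also removed; the
    ``FST_dataset`` keeps monomorphic and low-MAF loci.
    """
    if dataset not in (LD_DATASET, FST_DATASET):
        raise ValueError(f"unknown dataset tag {dataset!r}")

    # sample missingness first
    miss_frac = np.zeros(panel.n_samples)
    if panel.n_variants:
        per_hap = (panel.haplotypes == MISSING)
        miss_frac = per_hap.reshape(panel.n_samples, 2, -1).any(axis=1).mean(axis=1)
    keep_samples = miss_frac < max_sample_missing
    removed_ids = panel.samples.loc[~keep_samples, "sample_id"].tolist()
    if not keep_samples.any():
        raise PanelError("all samples removed by missingness filter")
    sub = panel.take_samples(np.flatnonzero(keep_samples))

    # variant filters, charged to the first matching reason
    reasons = {r: 0 for r in REASON_ORDER}
    drop = np.zeros(sub.n_variants, dtype=bool)
    charged = np.zeros(sub.n_variants, dtype=bool)

    unplaced = ~sub.variants["placed"].to_numpy()
    reasons["unplaced"] = int(unplaced.sum())
    drop |= unplaced
    charged |= unplaced

    if dataset == LD_DATASET:
        no_anc = (sub.variants["ancestral"].to_numpy() == ANCESTRAL_UNKNOWN) & ~charged
        reasons["no_ancestral"] = int(no_anc.sum())
        drop |= no_anc
        charged |= no_anc

        low = (sub.maf() < maf_min) & ~charged
        reasons["low_MAF"] = int(low.sum())
        drop |= low

    if drop.all():
        raise PanelError("no variants left after QC")
    out = sub.take_variants(np.flatnonzero(~drop))
    report = QCReport(dataset_tag=dataset, samples_removed=removed_ids,
                      variants_removed_by_reason=reasons)
    return out, report
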