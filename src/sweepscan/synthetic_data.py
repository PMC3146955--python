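"""Seeded generator of phased multi-population SNP panels.

The generator emulates a 50K-chip-like panel: a few tens of thousands of
autosomal biallelic SNPs, several populations whose allele frequencies diverge
from a shared ancestral frequency under the Balding-Nichols model, and
distance-decaying linkage disequilibrium produced by a founder-mosaic
(Li-Stephens-like) copying process.  Selective sweeps are injected afterwards
by copying one carrier haplotype over others around a core SNP, which creates
exactly the long-shared-haplotype signal that |iHS| targets.

Model, per chromosome and population:

1. ancestral frequency ``p_l ~ Uniform(maf_floor, 1 - maf_floor)`` per locus;
2. population frequency ``p_{l,k} ~ Beta(p_l (1-F_k)/F_k, (1-p_l)(1-F_k)/F_k)``
   (Balding-Nichols with divergence ``F_k``);
3. ``n_founders`` founder haplotypes drawn site-wise Bernoulli(``p_{l,k}``);
4. each sample haplotype copies a founder, re-choosing the founder between
   adjacent SNPs with probability ``1 - exp(-recomb_per_bp * gap)``;
5. SNP positions are sorted duplicate-free uniform draws on the chromosome.

Allele 0 is ancestral by construction, so the ancestral-state annotation is
exact.  All randomness derives from ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import write_hap_tsv, write_popmap, write_vcf
from .panel import HaplotypePanel, make_variant_table


@dataclasses.dataclass
class SweepSpec:
    """A selective sweep to inject: population, core locus, final frequency,
    and the mean one-sided extent (bp) of the conserved haplotype."""

    pop: str
    chrom: str
    core_pos: int
    f_target: float = 0.8
    L_sweep: float = 1_000_000.0

    def __post_init__(self) -> None:
        if not 0 < self.f_target <= 1:
            raise ValueError("f_target must be in (0, 1]")
        if self.L_sweep <= 0:
            raise ValueError("L_sweep must be > 0")


@dataclasses.dataclass
class SimConfig:
    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    n_snp_per_chrom: int = 1_000
    n_pop: int = 2
    n_diploid_per_pop: int = 50
    bn_F_per_pop: tuple[float, ...] = (0.1, 0.1)
    n_founders: int = 20
    recomb_per_bp: float = 2e-7
    maf_floor: float = 0.05
    sweeps: tuple[SweepSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bn_F_per_pop) != self.n_pop:
            raise ValueError("bn_F_per_pop length must equal n_pop")
        if any(not 0 < f < 1 for f in self.bn_F_per_pop):
            raise ValueError("each bn_F must lie in (0, 1)")
        if self.recomb_per_bp < 0:
            raise ValueError("recomb_per_bp must be >= 0")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        for field in ("n_chrom", "n_snp_per_chrom", "n_pop",
                      "n_diploid_per_pop", "n_founders", "chrom_length_bp"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")

    @property
    def populations(self) -> list[str]:
        return [f"pop{k + 1}" for k in range(self.n_pop)]


@dataclasses.dataclass
class TruthTable:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    ancestral_freq: np.ndarray            # (n_loci,)
    pop_freq: np.ndarray                  # (n_pop, n_loci) Balding-Nichols draws
    derived_counts: np.ndarray            # (n_loci,) panel-wide derived tallies
    sweeps: list[dict] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "ancestral_freq": self.ancestral_freq.tolist(),
            "pop_freq": self.pop_freq.tolist(),
            "derived_counts": self.derived_counts.tolist(),
            "sweeps": self.sweeps,
        })


# ----------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.sort(rng.integers(1, length + 1, size=n))
    while len(np.unique(pos)) < n:  # re-draw zero-gap duplicates
        dup = np.concatenate([[False], np.diff(pos) == 0])
        pos[dup] = rng.integers(1, length + 1, size=int(dup.sum()))
        pos = np.sort(pos)
    return pos


def _mosaic_haplotypes(rng, founders: np.ndarray, n_hap: int,
                       positions: np.ndarray, recomb_per_bp: float) -> np.ndarray:
    """Copy ``n_hap`` haplotypes from ``founders`` with distance-dependent
    founder switching between adjacent SNPs."""
    n_founders, n_snp = founders.shape
    gaps = np.diff(positions)
    p_switch = 1.0 - np.exp(-recomb_per_bp * gaps)
    out = np.empty((n_hap, n_snp), dtype=np.int8)
    cols = np.arange(n_snp)
    for h in range(n_hap):
        switch = rng.random(n_snp - 1) < p_switch
        seg = np.concatenate([[0], np.cumsum(switch)])
        founder_of_seg = rng.integers(0, n_founders, size=seg[-1] + 1)
        out[h] = founders[founder_of_seg[seg], cols]
    return out


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, TruthTable]:
    """Simulate a phased multi-population panel under ``cfg``.

    Returns the panel plus the :class:`TruthTable` of ancestral and
    per-population allele frequencies actually used.  Any sweeps listed in
    ``cfg.sweeps`` are injected after the neutral panel is built.
    """
    rng = np.random.default_rng(cfg.seed)
    n_loci = cfg.n_chrom * cfg.n_snp_per_chrom
    pops = cfg.populations

    p_anc = rng.uniform(cfg.maf_floor, 1 - cfg.maf_floor, size=n_loci)
    pop_freq = np.empty((cfg.n_pop, n_loci))
    for k, F in enumerate(cfg.bn_F_per_pop):
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        if np.any(a <= 0) or np.any(b <= 0) or not np.all(np.isfinite(a + b)):
            raise ValueError("degenerate Beta parameters (F too close to 0 or 1)")
        pop_freq[k] = rng.beta(a, b)

    chroms, positions = [], []
    for c in range(cfg.n_chrom):
        chroms += [f"chr{c + 1}"] * cfg.n_snp_per_chrom
        positions.append(_draw_positions(rng, cfg.n_snp_per_chrom,
                                         cfg.chrom_length_bp))
    positions = np.concatenate(positions)

    n_hap_per_pop = 2 * cfg.n_diploid_per_pop
    hap_blocks = []
    for k in range(cfg.n_pop):
        block = np.empty((n_hap_per_pop, n_loci), dtype=np.int8)
        for c in range(cfg.n_chrom):
            s = slice(c * cfg.n_snp_per_chrom, (c + 1) * cfg.n_snp_per_chrom)
            founders = (rng.random((cfg.n_founders, cfg.n_snp_per_chrom))
                        < pop_freq[k, s]).astype(np.int8)
            block[:, s] = _mosaic_haplotypes(rng, founders, n_hap_per_pop,
                                             positions[s], cfg.recomb_per_bp)
        hap_blocks.append(block)
    haps = np.concatenate(hap_blocks, axis=0)

    sample_ids, sample_pops = [], []
    for k, pop in enumerate(pops):
        for i in range(cfg.n_diploid_per_pop):
            sample_ids.append(f"{pop}_s{i + 1}")
            sample_pops.append(pop)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": sample_pops})

    variants = make_variant_table(
        ids=[f"snp{i + 1}" for i in range(n_loci)],
        chroms=chroms, pos=positions,
        ancestral=np.zeros(n_loci, dtype=np.int8),
    )
    panel = HaplotypePanel(haplotypes=haps, variants=variants, samples=samples)
    truth = TruthTable(ancestral_freq=p_anc, pop_freq=pop_freq,
                       derived_counts=(haps == 1).sum(axis=0))

    for spec in cfg.sweeps:
        panel, truth = inject_sweep(panel, truth, spec,
                                    seed=int(rng.integers(0, 2**31 - 1)))
    return panel, truth


def suitable_core_pos(panel: HaplotypePanel, chrom: str, pop: str | None = None,
                      freq_range: tuple[float, float] = (0.1, 0.5),
                      near: int | None = None) -> int:
    """Position of a SNP suitable as a sweep core: derived allele segregating
    at moderate frequency (a sweep acts on an allele that has not yet risen),
    nearest to ``near`` (chromosome midpoint by default)."""
    on = panel.variants["chrom"].to_numpy() == chrom
    pos = panel.variants["pos"].to_numpy()
    rows = panel.haplotype_rows_of(pop)
    f = (panel.haplotypes[rows] == 1).mean(axis=0)
    ok = on & (f > freq_range[0]) & (f < freq_range[1])
    if not ok.any():
        raise ValueError(f"no suitable core SNP on {chrom}")
    if near is None:
        near = int((pos[on].min() + pos[on].max()) // 2)
    cand = np.flatnonzero(ok)
    return int(pos[cand[np.argmin(np.abs(pos[cand] - near))]])


def inject_sweep(panel: HaplotypePanel, truth: TruthTable, spec: SweepSpec,
                 seed: int) -> tuple[HaplotypePanel, TruthTable]:
    """Overwrite haplotypes in the target population with copies of one carrier
    haplotype around the core SNP until the derived frequency reaches
    ``f_target``; each copy extends Exponential(``L_sweep``) bp to either side
    and keeps the recipient's original alleles outside that interval."""
    rng = np.random.default_rng(seed)
    on_chrom = np.flatnonzero(panel.variants["chrom"].to_numpy() == spec.chrom)
    if on_chrom.size == 0:
        raise ValueError(f"no SNPs on chromosome {spec.chrom}")
    pos = panel.variants["pos"].to_numpy()[on_chrom]
    core = on_chrom[np.argmin(np.abs(pos - spec.core_pos))]
    core_pos = int(panel.variants["pos"].iloc[core])

    rows = panel.haplotype_rows_of(spec.pop)
    H = panel.haplotypes.copy()
    carriers = rows[H[rows, core] == 1]
    if carriers.size == 0:
        raise ValueError(
            f"no derived-allele carrier at the snapped core {spec.chrom}:{core_pos}; "
            "re-seed the panel or choose another core position")
    donor = int(rng.choice(carriers))
    n_target = int(np.ceil(spec.f_target * rows.size))

    non_carriers = rows[H[rows, core] == 0]
    rng.shuffle(non_carriers)
    n_copy = max(0, n_target - carriers.size)
    dist = np.abs(panel.variants["pos"].to_numpy() - core_pos)
    same_chrom = panel.variants["chrom"].to_numpy() == spec.chrom
    for r in non_carriers[:n_copy]:
        d_left, d_right = rng.exponential(spec.L_sweep, size=2)
        left_of = (panel.variants["pos"].to_numpy() < core_pos)
        inside = same_chrom & (
            (left_of & (dist <= d_left)) | (~left_of & (dist <= d_right)))
        H[r, inside] = H[donor, inside]

    out = HaplotypePanel(haplotypes=H, variants=panel.variants.copy(),
                         samples=panel.samples.copy())
    realized = float((H[rows, core] == 1).mean())
    truth = dataclasses.replace(truth, sweeps=truth.sweeps + [{
        "pop": spec.pop, "chrom": spec.chrom, "core_index": int(core),
        "core_pos": core_pos, "f_target": spec.f_target,
        "realized_freq": realized, "L_sweep": spec.L_sweep,
        "carrier_rows": np.flatnonzero(out.haplotypes[:, core] == 1).tolist(),
    }])
    return out, truth


# ----------------------------------------------------------------------

def random_gene_bed(chrom_lengths: dict[str, int],
                    density_per_mb: dict[str, float] | float,
                    seed: int, gene_length_bp: int = 20_000) -> pd.DataFrame:
    """Toy gene annotation: non-overlapping intervals at a per-chromosome (or
    uniform) density, 0-based half-open.  ``density_per_mb`` may map chromosome
    names to densities to create gene-rich and gene-poor tracts."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        dens = (density_per_mb.get(chrom, 0.0)
                if isinstance(density_per_mb, dict) else density_per_mb)
        n = rng.poisson(dens * length / 1e6)
        starts = np.sort(rng.integers(0, max(1, length - gene_length_bp), size=n))
        prev_end = -1
        for i, s in enumerate(starts):
            s = max(s, prev_end)  # enforce non-overlap
            e = min(s + gene_length_bp, length)
            if e <= s:
                continue
            rows.append((chrom, int(s), int(e), f"{chrom}_g{i + 1}"))
            prev_end = e
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False, header=False)


def write_fixtures(panel: HaplotypePanel, truth: TruthTable,
                   outdir: str | Path, genes: pd.DataFrame | None = None,
                   overwrite: bool = False) -> dict[str, Path]:
    """Emit hap_tsv, popmap, VCF, gene BED and truth JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hap_tsv": outdir / "panel.hap.tsv",
        "popmap": outdir / "popmap.tsv",
        "vcf": outdir / "panel.vcf",
        "bed": outdir / "genes.bed",
        "truth": outdir / "truth.json",
    }
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(f"refusing to overwrite {clashes[0]}")
    write_hap_tsv(panel, paths["hap_tsv"])
    write_popmap(panel.samples, paths["popmap"])
    write_vcf(panel, paths["vcf"])
    if genes is None:
        lengths = {c: int(g["pos"].max()) + 1
                   for c, g in panel.variants.groupby("chrom", sort=False)}
        genes = random_gene_bed(lengths, density_per_mb=5.0, seed=0)
    write_bed(genes, paths["bed"])
    paths["truth"].write_text(truth.to_json())
    return paths
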