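import numpy as np
import pandas as pd
import pytest

from sweepscan.panel import HaplotypePanel, make_variant_table
from sweepscan import SimConfig, SweepSpec, simulate_panel, inject_sweep
from sweepscan.synthetic_data import suitable_core_pos


def build_panel(haps, pos, chroms=None, ancestral=None, pops=None):
    """Hand-build a small panel from a list of haplotype strings/lists."""
    H = np.array([[int(c) if c != "." else -1 for c in row] for row in haps],
                 dtype=np.int8)
    n_var = H.shape[1]
    n_samp = H.shape[0] // 2
    if chroms is None:
        chroms = ["chr1"] * n_var
    variants = make_variant_table(
        ids=[f"snp{i}" for i in range(n_var)], chroms=chroms, pos=pos,
        ancestral=np.zeros(n_var, dtype=np.int8) if ancestral is None else ancestral)
    if pops is None:
        pops = ["popA"] * n_samp
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_samp)],
                            "population": pops})
    return HaplotypePanel(haplotypes=H, variants=variants, samples=samples)


@pytest.fixture(scope="session")
def neutral_panel():
    """One population, one chromosome, moderate LD; no sweep."""
    cfg = SimConfig(n_chrom=1, chrom_length_bp=50_000_000, n_snp_per_chrom=600,
                    n_pop=1, n_diploid_per_pop=50, bn_F_per_pop=(0.1,),
                    seed=11)
    panel, truth = simulate_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def two_pop_panel():
    cfg = SimConfig(n_chrom=2, chrom_length_bp=40_000_000, n_snp_per_chrom=400,
                    n_pop=2, n_diploid_per_pop=40, bn_F_per_pop=(0.2, 0.2),
                    seed=23)
    panel, truth = simulate_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def sweep_panel():
    """Strong one-population sweep at a known core."""
    cfg = SimConfig(n_chrom=1, chrom_length_bp=50_000_000, n_snp_per_chrom=800,
                    n_pop=1, n_diploid_per_pop=50, bn_F_per_pop=(0.1,), seed=5)
    panel, truth = simulate_panel(cfg)
    core = suitable_core_pos(panel, "chr1", "pop1")
    spec = SweepSpec(pop="pop1", chrom="chr1", core_pos=core,
                     f_target=0.8, L_sweep=1_000_000)
    panel, truth = inject_sweep(panel, truth, spec, seed=7)
    return panel, truth
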