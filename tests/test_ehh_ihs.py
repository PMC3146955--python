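import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import LD_DATASET, qc_filter
from sweepscan.ehh_ihs import (EHHCurve, ehh_at, ehh_curve, ihh, ihs_raw,
                               ihs_scan, split_half_validation,
                               standardize_ihs)

from conftest import build_panel


def brute_force_ehh(H, rows, lo, hi):
    """Independent oracle: enumerate all carrier pairs and count identical
    sub-haplotypes over the closed column interval [lo, hi]."""
    subs = [tuple(H[r, lo:hi + 1]) for r in rows]
    pairs = list(itertools.combinations(subs, 2))
    return sum(a == b for a, b in pairs) / len(pairs)


class TestEhhAt:
    def test_all_identical_carriers(self):
        panel = build_panel(["111", "111", "111", "111", "000", "000"],
                            pos=[10, 20, 30])
        assert ehh_at(panel, 0, "derived", 2) == pytest.approx(1.0)

    def test_one_identical_pair_of_six(self):
        """Carrier sub-haplotypes {AB, AB, AC, BC}: 1 identical pair of 6."""
        # core col 0 all derived; cols 1-2 encode AB, AB, AC, BC
        panel = build_panel(["100", "100", "101", "110", "011", "011"],
                            pos=[10, 20, 30])
        assert ehh_at(panel, 0, "derived", 2) == pytest.approx(1 / 6)

    def test_all_distinct(self):
        panel = build_panel(["100", "101", "110", "111", "000", "000"],
                            pos=[10, 20, 30])
        assert ehh_at(panel, 0, "derived", 2) == pytest.approx(0.0)

    def test_fewer_than_two_carriers_errors(self):
        panel = build_panel(["10", "00", "00", "00"], pos=[10, 20])
        with pytest.raises(ValueError, match="EHH undefined"):
            ehh_at(panel, 0, "derived", 1)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_enumeration(self, seed):
        """EHH equals the pair-enumeration oracle on random small panels."""
        rng = np.random.default_rng(seed)
        n_hap = rng.integers(4, 13) * 2 // 2 * 2  # even, 4..12
        n_snp = int(rng.integers(3, 11))
        H = rng.integers(0, 2, size=(n_hap, n_snp))
        panel = build_panel(H.astype(str).tolist(),
                            pos=(np.arange(n_snp) * 100 + 1).tolist())
        core = int(rng.integers(0, n_snp))
        for allele, code in (("ancestral", 0), ("derived", 1)):
            rows = np.flatnonzero(H[:, core] == code)
            if rows.size < 2:
                continue
            target = int(rng.integers(0, n_snp))
            expected = brute_force_ehh(H, rows, min(core, target),
                                       max(core, target))
            assert ehh_at(panel, core, allele, target) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_monotone_refinement(self, seed):
        """EHH never increases as the interval widens on either side."""
        rng = np.random.default_rng(seed)
        H = rng.integers(0, 2, size=(10, 10))
        panel = build_panel(H.astype(str).tolist(),
                            pos=(np.arange(10) * 50 + 1).tolist())
        core = 5
        for allele, code in (("ancestral", 0), ("derived", 1)):
            if (H[:, core] == code).sum() < 2:
                continue
            vals = [ehh_at(panel, core, allele, t) for t in range(5, 10)]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestEhhCurve:
    def test_core_at_chromosome_end(self):
        panel = build_panel(["1100", "1100", "1010", "0110"],
                            pos=[10, 20, 30, 40])
        curve = ehh_curve(panel, 0, "derived")
        assert curve.left == []
        assert not curve.left_reached

    def test_stops_at_floor_crossing_marker(self):
        """The first marker with EHH < floor is kept as the crossing anchor."""
        # derived carriers at col0: rows 0-3; cols separate them progressively
        panel = build_panel(["1000", "1011", "1101", "1110",
                             "0000", "0000"], pos=[10, 20, 30, 40])
        curve = ehh_curve(panel, 0, "derived", ehh_floor=0.05)
        assert curve.right_reached
        assert curve.right[-1][1] < 0.05
        # nothing beyond the anchor marker was evaluated
        assert len(curve.right) <= 3


class TestIhh:
    def test_hand_trapezoid_with_interpolated_crossing(self):
        """EHH (1.0, 0.5, 0.04) at 0/1000/2000 bp: area ~ 1019.02."""
        curve = EHHCurve(core=0, allele="derived", core_pos=0,
                         left=[], right=[(1000, 0.5), (2000, 0.04)],
                         left_reached=True, right_reached=True, n_carriers=4)
        area, valid = ihh(curve)
        # one-sided: 750 + (0.5+0.05)/2 * 978.2609 = 1019.0217
        assert valid
        assert area == pytest.approx(1019.0217, abs=0.01)

    def test_single_trapezoid(self):
        """1.0 at the core, 0.04 at 100 bp: crossing at 98.96, area 51.95."""
        curve = EHHCurve(core=0, allele="derived", core_pos=0,
                         left=[], right=[(100, 0.04)],
                         left_reached=True, right_reached=True, n_carriers=4)
        area, _ = ihh(curve)
        assert area == pytest.approx(51.953125, abs=1e-6)

    def test_symmetric_sides_double(self):
        one = EHHCurve(core=0, allele="derived", core_pos=0,
                       left=[], right=[(1000, 0.5), (2000, 0.04)],
                       left_reached=True, right_reached=True, n_carriers=4)
        both = EHHCurve(core=0, allele="derived", core_pos=0,
                        left=[(-1000, 0.5), (-2000, 0.04)],
                        right=[(1000, 0.5), (2000, 0.04)],
                        left_reached=True, right_reached=True, n_carriers=4)
        a1, _ = ihh(one)
        a2, _ = ihh(both)
        assert a2 == pytest.approx(2 * a1)

    def test_edge_policies(self):
        curve = EHHCurve(core=0, allele="derived", core_pos=0,
                         left=[], right=[(1000, 0.5)],
                         left_reached=True, right_reached=False, n_carriers=4)
        _, valid_excl = ihh(curve, truncation="exclude")
        area_trunc, valid_trunc = ihh(curve, truncation="truncate")
        assert not valid_excl
        assert valid_trunc and area_trunc == pytest.approx(750.0)


class TestIhsRaw:
    @pytest.mark.parametrize("a,d,expected", [
        (2000.0, 1000.0, np.log(2)),
        (1000.0, 1000.0, 0.0),
        (1000.0, 2000.0, -np.log(2)),
    ])
    def test_log_ratio(self, a, d, expected):
        assert ihs_raw(a, d) == pytest.approx(expected)

    def test_antisymmetry(self):
        assert ihs_raw(1234.0, 777.0) == pytest.approx(-ihs_raw(777.0, 1234.0))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ihs_raw(0.0, 100.0)


class TestStandardize:
    @staticmethod
    def _records(raw, freq=None, valid=None):
        n = len(raw)
        return pd.DataFrame({
            "derived_freq": freq if freq is not None else [0.5] * n,
            "ihs_raw": raw,
            "valid": valid if valid is not None else [True] * n,
            "reason": [""] * n,
        })

    def test_three_known_values(self):
        """Raw (0.693, 1.386, 2.079) standardize to (-1, 0, 1)."""
        out = standardize_ihs(self._records([0.693, 1.386, 2.079]))
        assert out["ihs_std"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_bin_moments_exact(self):
        rng = np.random.default_rng(0)
        out = standardize_ihs(self._records(
            rng.normal(size=500), freq=rng.uniform(0.02, 0.98, 500)))
        for _, grp in out[out["valid"]].groupby("freq_bin"):
            assert abs(grp["ihs_std"].mean()) < 1e-12
            assert abs(grp["ihs_std"].var(ddof=1) - 1) < 1e-12

    def test_invalid_records_left_unstandardized(self):
        out = standardize_ihs(self._records(
            [0.1, 0.2, 0.3, 9.9], valid=[True, True, True, False]))
        assert np.isnan(out["ihs_std"].iloc[3])
        assert not out["valid"].iloc[3]

    def test_small_bins_merged(self):
        """Records spread over many bins merge until each group is full."""
        rng = np.random.default_rng(1)
        out = standardize_ihs(self._records(
            rng.normal(size=40), freq=rng.uniform(0.02, 0.98, 40)),
            n_bins=20, min_bin_count=10)
        counts = out[out["valid"]].groupby("freq_bin").size()
        assert (counts >= 10).all()


class TestScan:
    def test_sweep_core_is_extreme(self, sweep_panel):
        panel, truth = sweep_panel
        ld, _ = qc_filter(panel, LD_DATASET)
        scan = ihs_scan(ld)
        v = scan[scan["valid"]]
        thr = v["abs_ihs"].quantile(0.95)
        core_row = scan[scan["pos"] == truth.sweeps[0]["core_pos"]].iloc[0]
        assert core_row["valid"]
        assert core_row["abs_ihs"] > thr

    def test_empirical_tail_fraction(self, neutral_panel):
        """By construction of the empirical quantile, ~5% of valid SNPs
        exceed the 95th percentile of abs_ihs."""
        panel, _ = neutral_panel
        ld, _ = qc_filter(panel, LD_DATASET)
        scan = ihs_scan(ld)
        v = scan[scan["valid"]]
        frac = (v["abs_ihs"] > v["abs_ihs"].quantile(0.95)).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_fixed_derived_allele_invalid(self):
        H = np.array([[1, 0, 1], [1, 1, 0], [1, 0, 0], [1, 1, 1]])
        panel = build_panel(H.astype(str).tolist(), pos=[10, 2000, 4000])
        scan = ihs_scan(panel)
        row = scan[scan["pos"] == 10].iloc[0]
        assert not row["valid"]
        assert row["reason"] == "few_carriers"

    def test_position_rescaling_leaves_raw_score_unchanged(self, neutral_panel):
        """ihs_raw is invariant under a global rescaling of positions."""
        panel, _ = neutral_panel
        ld, _ = qc_filter(panel, LD_DATASET)
        sub = ld.take_variants(np.arange(80))
        scan1 = ihs_scan(sub)
        scaled = sub.take_variants(np.arange(80))
        scaled.variants["pos"] *= 10
        scan2 = ihs_scan(scaled)
        v = scan1["valid"] & scan2["valid"]
        assert np.allclose(scan1.loc[v, "ihs_raw"], scan2.loc[v, "ihs_raw"])

    def test_short_chromosome_skipped(self):
        panel = build_panel(["10", "01", "11", "00"], pos=[10, 20],
                            chroms=["chr1", "chr2"])
        with pytest.raises(ValueError, match="no scannable"):
            with pytest.warns(UserWarning):
                ihs_scan(panel)


class TestSplitHalf:
    def test_identical_halves_correlate_perfectly(self, neutral_panel):
        """Duplicating every individual and splitting into the two copies
        gives correlation 1."""
        panel, _ = neutral_panel
        ld, _ = qc_filter(panel, LD_DATASET)
        small = ld.take_variants(np.arange(150))
        idx = np.arange(small.n_samples)
        doubled = small.take_samples(np.repeat(idx, 2))
        doubled.samples["sample_id"] = [f"d{i}" for i in range(doubled.n_samples)]
        s1, s2, r = split_half_validation(
            doubled, seed=0,
            split=(np.arange(0, doubled.n_samples, 2),
                   np.arange(1, doubled.n_samples, 2)))
        assert r == pytest.approx(1.0)

    def test_seeded_determinism(self, neutral_panel):
        panel, _ = neutral_panel
        ld, _ = qc_filter(panel, LD_DATASET)
        small = ld.take_variants(np.arange(120))
        _, _, r1 = split_half_validation(small, seed=42)
        _, _, r2 = split_half_validation(small, seed=42)
        assert r1 == r2

    def test_too_few_individuals(self):
        panel = build_panel(["101", "110", "011", "000"], pos=[10, 20, 30])
        with pytest.raises(ValueError, match="20 diploid"):
            split_half_validation(panel, seed=0)
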