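"""Hill-Weir decay model, extents, LD windows and genome coverage."""

import numpy as np
import pandas as pd
import pytest

from ldgwas.core import GeneticMap, RecombProfile, recomb_profile
from ldgwas.decay import (LDDecayFit, LDWindowTable, build_ld_windows,
                          coverage_profile, fit_hill_weir, genome_coverage,
                          hill_weir_expectation, ld_extent, union_intervals)

from conftest import make_panel


def _model_pairs(beta, n_sample, n_pairs, sigma, seed, scale="cM", max_d=1.0):
    rng = np.random.default_rng(seed)
    d = rng.uniform(1e-4, max_d, size=n_pairs)
    r2 = hill_weir_expectation(beta * d, n_sample) + rng.normal(0, sigma, n_pairs)
    return pd.DataFrame({
        "chrom": 1, "d_cM": d if scale == "cM" else d / 1e6,
        "d_bp": d * 1e6 if scale == "cM" else d,
        "r2K": np.clip(r2, 0, 1),
    })


class TestHillWeirModel:
    def test_value_at_zero_distance(self):
        # (10/22) * (1 + 36/(22 n)); n = 247 -> ~0.4575
        assert hill_weir_expectation(0.0, 247) == pytest.approx(0.4575, abs=5e-4)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 50, 200)
        vals = hill_weir_expectation(d, 100)
        assert np.all(np.diff(vals) < 0)


class TestFit:
    def test_beta_recovery(self):
        pairs = _model_pairs(beta=50.0, n_sample=247, n_pairs=10_000,
                             sigma=0.05, seed=42)
        fit = fit_hill_weir(pairs, "cM", n_sample=247)
        assert fit.beta == pytest.approx(50.0, rel=0.10)

    def test_scale_equivariance(self):
        pairs = _model_pairs(beta=50.0, n_sample=200, n_pairs=5000,
                             sigma=0.02, seed=1)
        fit1 = fit_hill_weir(pairs, "cM", n_sample=200)
        doubled = pairs.assign(d_cM=2 * pairs["d_cM"])
        fit2 = fit_hill_weir(doubled, "cM", n_sample=200)
        assert fit2.beta == pytest.approx(fit1.beta / 2, rel=1e-3)

    def test_zero_distances_excluded_and_min_pairs(self):
        pairs = _model_pairs(50.0, 200, 120, 0.01, 2)
        pairs.loc[:50, "d_cM"] = 0.0
        with pytest.raises(ValueError, match="usable pairs"):
            fit_hill_weir(pairs, "cM", n_sample=200)


class TestExtent:
    def _fit(self, beta=10.0, n=247):
        return LDDecayFit(1, "HIGH", "cM", beta, n, 0.0)

    def test_threshold_above_curve_start(self):
        assert ld_extent(self._fit(), 0.46) == 0.0

    def test_monotone_thresholds(self):
        f = self._fit()
        e = {t: ld_extent(f, t) for t in (0.1, 0.2, 0.4)}
        assert e[0.1] >= e[0.2] >= e[0.4] >= 0

    def test_grid_scan_oracle(self):
        f = self._fit(beta=7.0)
        for t in (0.1, 0.2, 0.4):
            root = ld_extent(f, t)
            grid = np.arange(0, 5, 1e-6)
            vals = hill_weir_expectation(f.beta * grid, f.n_sample)
            brute = grid[np.argmax(vals <= t)]
            assert root == pytest.approx(brute, abs=2e-6)


class TestWindows:
    def _setup(self):
        # uniform 1 cM/Mbp HIGH map plus a LOW map variant
        gmap = GeneticMap(pd.DataFrame({
            "chrom": [1, 1], "pos_bp": [1, 20_000_000], "pos_cM": [0.0, 20.0]}))
        prof = recomb_profile(gmap)
        return gmap, prof

    def test_low_region_physical_window(self):
        # LOW marker at 10 Mbp with 629 kbp physical extent -> +-629000
        gmap = GeneticMap(pd.DataFrame({
            "chrom": [1, 1], "pos_bp": [1, 20_000_000], "pos_cM": [0.0, 2.0]}))
        prof = recomb_profile(gmap)  # 0.1 cM/Mbp everywhere -> LOW
        G = make_panel(np.array([[0], [1], [0], [1], [0], [1]], dtype=float),
                       pos=[10_000_000], cm=[1.0])
        fit = LDDecayFit(1, "LOW", "bp", 1.0, 6, 0.0)
        fit.extents = {0.1: 629_000.0, 0.2: 300_000.0, 0.4: 100_000.0}
        wt = build_ld_windows(G, {(1, "LOW"): fit}, prof, gmap, threshold=0.1)
        row = wt.windows.iloc[0]
        assert (row["start_bp"], row["end_bp"]) == (10_000_000 - 629_000,
                                                    10_000_000 + 629_000)

    def test_high_region_zero_extent_single_position(self):
        gmap, prof = self._setup()
        G = make_panel(np.array([[0], [1], [0], [1]], dtype=float),
                       pos=[5_000_000], cm=[5.0])
        fit = LDDecayFit(1, "HIGH", "cM", 1.0, 4, 0.0)
        fit.extents = {0.1: 0.0}
        wt = build_ld_windows(G, {(1, "HIGH"): fit}, prof, gmap)
        row = wt.windows.iloc[0]
        assert row["start_bp"] == row["end_bp"] == 5_000_000

    def test_clipping_at_chromosome_start(self):
        gmap, prof = self._setup()
        G = make_panel(np.array([[0], [1], [0], [1]], dtype=float),
                       pos=[100_000], cm=[0.1])
        fit = LDDecayFit(1, "HIGH", "cM", 1.0, 4, 0.0)
        fit.extents = {0.1: 1.0}  # 1 cM ~ 1 Mbp here
        wt = build_ld_windows(G, {(1, "HIGH"): fit}, prof, gmap)
        assert wt.windows.iloc[0]["start_bp"] == 1

    def test_bed_export_is_half_open(self, tmp_path):
        gmap, prof = self._setup()
        G = make_panel(np.array([[0], [1], [0], [1]], dtype=float),
                       pos=[5_000_000], cm=[5.0])
        fit = LDDecayFit(1, "HIGH", "cM", 1.0, 4, 0.0)
        fit.extents = {0.1: 0.1}
        wt = build_ld_windows(G, {(1, "HIGH"): fit}, prof, gmap)
        wt.to_bed(tmp_path / "w.bed")
        bed = pd.read_csv(tmp_path / "w.bed", sep="\t", header=None)
        assert bed.iloc[0, 1] == wt.windows.iloc[0]["start_bp"] - 1


class TestCoverage:
    def _gmap(self, length=10_000_000):
        return GeneticMap(pd.DataFrame({
            "chrom": [1, 1], "pos_bp": [1, length], "pos_cM": [0.0, 10.0]}))

    def _wt(self, intervals):
        return LDWindowTable(pd.DataFrame(
            [("m%d" % k, 1, (s + e) // 2, s, e, "HIGH", False)
             for k, (s, e) in enumerate(intervals)],
            columns=["marker_id", "chrom", "pos_bp", "start_bp", "end_bp",
                     "region_class", "flagged"],
        ))

    def test_full_and_partial_coverage(self):
        gmap = self._gmap()
        full = genome_coverage(self._wt([(1, 10_000_000)]), gmap)
        assert full.iloc[0]["physical_fraction"] == pytest.approx(1.0)
        two = genome_coverage(
            self._wt([(1, 1_000_000), (5_000_001, 6_000_000)]), gmap)
        assert two.iloc[0]["physical_fraction"] == pytest.approx(0.2, abs=1e-6)

    def test_occupancy_mask_oracle(self):
        rng = np.random.default_rng(8)
        L = 1_000_000
        gmap = GeneticMap(pd.DataFrame({
            "chrom": [1, 1], "pos_bp": [1, L], "pos_cM": [0.0, 1.0]}))
        s = rng.integers(1, L - 20_000, size=60)
        e = s + rng.integers(1, 20_000, size=60)
        cov = genome_coverage(self._wt(list(zip(s, e))), gmap)
        # brute-force 1-kbp (here 1-bp for exactness at small L) occupancy
        mask = np.zeros(L + 1, dtype=bool)
        for a, b in zip(s, e):
            mask[a : b + 1] = True
        assert cov.iloc[0]["covered_bp"] == mask.sum()

    def test_union_monotone_in_markers(self):
        gmap = self._gmap()
        small = genome_coverage(self._wt([(100, 200)]), gmap)
        more = genome_coverage(self._wt([(100, 200), (50_000, 90_000)]), gmap)
        assert more.iloc[0]["covered_bp"] >= small.iloc[0]["covered_bp"]

    def test_profile_conservation(self):
        gmap = self._gmap()
        wt = self._wt([(100, 50_000), (2_000_000, 2_700_000), (2_500_000, 3_200_000)])
        prof = coverage_profile(wt, gmap, window_sizes_kbp=(500,))
        covered = (prof["covered_fraction"] *
                   (prof["end_bp"] - prof["start_bp"] + 1)).sum()
        union = genome_coverage(wt, gmap).iloc[0]["covered_bp"]
        assert covered == pytest.approx(union, abs=1.0)

    def test_profile_inside_and_outside(self):
        gmap = self._gmap()
        wt = self._wt([(1, 600_000)])
        prof = coverage_profile(wt, gmap, window_sizes_kbp=(500,))
        assert prof.iloc[0]["covered_fraction"] == pytest.approx(1.0)
        assert prof.iloc[-1]["covered_fraction"] == 0.0
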