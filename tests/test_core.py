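"""Data model, I/O, QC filters, map projection and panel merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldgwas.core import (DataError, GeneticMap, GenotypeMatrix, filter_individuals,
                         filter_markers, merge_panels, project_position,
                         read_dose_table, read_genotypes, recomb_profile,
                         write_dose_table)

from conftest import make_markers, make_panel

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\tD
"""


def _write_vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadGenotypes:
    def test_vcf_dose_coding(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.\n",
        )
        G = read_genotypes(p, "vcf")
        np.testing.assert_array_equal(G.dose[:, 0], [0.0, 0.5, 1.0, np.nan])

    def test_vcf_duplicate_positions_rejected(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
            "1\t100\ts2\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n",
        )
        with pytest.raises(DataError, match="1:100"):
            read_genotypes(p, "vcf")

    def test_vcf_multiallelic_skipped(self, tmp_path):
        p = _write_vcf(
            tmp_path,
            "1\t100\ts1\tA\tG,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n"
            "1\t200\ts2\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0\n",
        )
        with pytest.warns(UserWarning, match="multiallelic"):
            G = read_genotypes(p, "vcf")
        assert G.n_markers == 1

    def test_dose_table_round_trip(self, tmp_path):
        G = make_panel([[0, 0.5, 1], [1, np.nan, 0]])
        write_dose_table(G, tmp_path / "g.dose.tsv", tmp_path / "g.markers.tsv")
        G2 = read_dose_table(tmp_path / "g.dose.tsv", tmp_path / "g.markers.tsv")
        assert G2.line_ids == G.line_ids
        np.testing.assert_array_equal(G2.dose, G.dose)
        pd.testing.assert_frame_equal(
            G2.markers[["marker_id", "chrom", "pos_bp"]],
            G.markers[["marker_id", "chrom", "pos_bp"]],
        )


class TestStructuralInvariants:
    def test_unsorted_markers_rejected(self):
        with pytest.raises(DataError, match="sorted"):
            make_panel([[0, 1]], pos=[2000, 1000])

    def test_bad_dose_alphabet_rejected(self):
        with pytest.raises(DataError, match="dose"):
            make_panel([[0.3, 1]])


class TestFilters:
    def test_missing_rate_filter(self):
        # 30% missing marker removed at max_missing=0.20
        dose = np.zeros((10, 2))
        dose[:3, 0] = np.nan
        dose[::2, 1] = 1.0
        G = filter_markers(make_panel(dose), max_missing=0.20, min_maf=0.0)
        assert G.markers["marker_id"].tolist() == ["m2"]

    def test_maf_threshold_boundary(self):
        dose = np.zeros((10, 1))
        dose[0, 0] = 1.0  # MAF = 0.10
        G = make_panel(dose)
        assert filter_markers(G, min_maf=0.05).n_markers == 1
        with pytest.warns(UserWarning, match="every marker"):
            assert filter_markers(G, min_maf=0.15).n_markers == 0

    def test_toy_enumeration_oracle(self):
        # 5 markers: one violates het, one missing, one MAF; 2 survive.
        n = 10
        dose = np.tile([0.0], (n, 5))
        dose[:5, 0] = 1.0          # fine: MAF 0.5
        dose[::1, 1] = 0.5         # all het -> het rate 1
        dose[:3, 2] = np.nan       # 30% missing
        dose[0, 3] = 1.0           # MAF 0.1 < 0.15
        dose[:4, 4] = 1.0          # fine: MAF 0.4
        G = make_panel(dose)
        # independent brute-force oracle
        expect = []
        for k in range(5):
            col = dose[:, k]
            called = col[~np.isnan(col)]
            het = (called == 0.5).mean()
            miss = np.isnan(col).mean()
            p = called.mean()
            if het <= 0.15 and miss <= 0.20 and min(p, 1 - p) >= 0.15:
                expect.append(f"m{k+1}")
        got = filter_markers(G, max_het=0.15, max_missing=0.20, min_maf=0.15)
        assert got.markers["marker_id"].tolist() == expect == ["m1", "m5"]

    def test_filter_idempotent(self, sim_panel):
        once = filter_markers(sim_panel)
        twice = filter_markers(once)
        assert once.n_markers == twice.n_markers
        np.testing.assert_array_equal(once.dose, twice.dose)

    def test_individual_filters(self):
        dose = np.zeros((4, 50))
        dose[1, :4] = 0.5            # 8% het -> removed
        dose[2, :6] = np.nan         # 12% missing -> removed
        dose[3, ::2] = 1.0           # fully called homozygous -> kept
        G = filter_individuals(make_panel(dose))
        assert G.line_ids == ["L1", "L4"]


class TestProjection:
    def test_anchor_exact_and_midpoint(self, two_anchor_map):
        assert project_position(two_anchor_map, 1, 1_000_000) == pytest.approx(1.0)
        assert project_position(two_anchor_map, 1, 3_000_000) == pytest.approx(5.0)
        # two anchors: the monotone interpolant is the straight line
        assert project_position(two_anchor_map, 1, 2_000_000) == pytest.approx(3.0)

    def test_round_trip(self, sim_map):
        rng = np.random.default_rng(0)
        bp = rng.uniform(1, sim_map.chrom_length_bp[1], size=100)
        cm = project_position(sim_map, 1, bp, "bp_to_cM")
        back = project_position(sim_map, 1, cm, "cM_to_bp")
        assert np.max(np.abs(back - bp)) < 1.0

    def test_missing_chromosome(self, two_anchor_map):
        with pytest.raises(DataError, match="absent"):
            project_position(two_anchor_map, 9, 1_500_000)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0.1, 10.0), min_size=3, max_size=8),
           st.floats(0.0, 1.0))
    def test_monotone_on_random_maps(self, rates, frac):
        # build a valid map from random per-Mbp rates; check monotonicity
        bp = np.arange(len(rates) + 1) * 1_000_000 + 1
        cm = np.concatenate([[0.0], np.cumsum(rates)])
        gmap = GeneticMap(pd.DataFrame({"chrom": 1, "pos_bp": bp, "pos_cM": cm}))
        q = np.sort([1 + frac * (bp[-1] - 1), bp[-1] - frac * (bp[-1] - 1)])
        out = project_position(gmap, 1, q, "bp_to_cM")
        assert out[0] <= out[1] + 1e-12


class TestRecombProfile:
    def _uniform_map(self, rate, length=10_000_000):
        return GeneticMap(pd.DataFrame({
            "chrom": [1, 1], "pos_bp": [1, length],
            "pos_cM": [0.0, rate * length / 1e6],
        }))

    def test_uniform_high_and_low(self):
        high = recomb_profile(self._uniform_map(1.0))
        assert (high.windows["region_class"] == "HIGH").all()
        low = recomb_profile(self._uniform_map(0.1))
        assert (low.windows["region_class"] == "LOW").all()

    def test_piecewise_flip(self):
        # 0.1 cM/Mbp for 10 Mbp, then 2.0 cM/Mbp for 10 Mbp
        gmap = GeneticMap(pd.DataFrame({
            "chrom": [1, 1, 1],
            "pos_bp": [1, 10_000_000, 20_000_000],
            "pos_cM": [0.0, 1.0, 21.0],
        }))
        prof = recomb_profile(gmap)
        cls = prof.windows["region_class"].tolist()
        assert cls[:4] == ["LOW"] * 4 and cls[-4:] == ["HIGH"] * 4


class TestMergePanels:
    def test_disjoint_union(self):
        a = make_panel(np.zeros((3, 3)), pos=[1000, 2000, 3000])
        b = make_panel(np.zeros((3, 4)), pos=[1500, 2500, 3500, 4500])
        assert merge_panels([a, b]).n_markers == 7

    def test_duplicate_keeps_one_with_union_tags(self):
        a = make_panel([[0], [1]], pos=[1000])
        a.markers.loc[0, "tech_tags"] = "ARRAY_LOW"
        b = make_panel([[0], [1]], pos=[1000])
        b.markers.loc[0, "tech_tags"] = "SEQ"
        m = merge_panels([a, b])
        assert m.n_markers == 1
        assert m.markers.loc[0, "tech_tags"] == "ARRAY_LOW,SEQ"

    def test_conflicting_alleles_dropped(self):
        a = make_panel([[0], [1]], pos=[1000])
        b = make_panel([[0], [1]], pos=[1000])
        b.markers.loc[0, "allele_labels"] = "C/T"
        with pytest.warns(UserWarning, match="conflicting"):
            m = merge_panels([a, b])
        assert m.n_markers == 0

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=10, unique=True),
           st.lists(st.integers(1, 30), min_size=1, max_size=10, unique=True))
    def test_union_count_oracle(self, pos_a, pos_b):
        a = make_panel(np.zeros((2, len(pos_a))), pos=[p * 100 for p in sorted(pos_a)])
        b = make_panel(np.zeros((2, len(pos_b))), pos=[p * 100 for p in sorted(pos_b)])
        m = merge_panels([a, b])
        assert m.n_markers == len(set(pos_a) | set(pos_b))
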