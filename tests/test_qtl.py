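"""LD-based QTL grouping, summaries, colocalization and local haplotypes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from ldgwas.decay import LDWindowTable
from ldgwas.qtl import (colocalize, group_ld_adj, group_ld_win, local_haplotypes,
                        stability_table, summarize_qtl)

from conftest import make_panel


def _windows(intervals, chrom=None):
    chrom = chrom or [1] * len(intervals)
    return LDWindowTable(pd.DataFrame(
        [(f"m{k+1}", chrom[k], (s + e) // 2, s, e, "HIGH", False)
         for k, (s, e) in enumerate(intervals)],
        columns=["marker_id", "chrom", "pos_bp", "start_bp", "end_bp",
                 "region_class", "flagged"],
    ))


def _assoc(markers, chrom=None, pos=None, neglog10p=None, env="e1", trait="t"):
    n = len(markers)
    chrom = chrom or [1] * n
    pos = pos or list(range(100, 100 * n + 1, 100))
    neglog10p = neglog10p if neglog10p is not None else [6.0] * n
    return pd.DataFrame({
        "marker_id": markers, "chrom": chrom, "pos_bp": pos, "trait": trait,
        "environment": env, "effect": 1.0, "p_value": 10.0 ** (-np.array(neglog10p)),
        "neglog10p": neglog10p, "maf": 0.3, "n_used": 100,
    })


def _brute_force_components(intervals):
    """Union-find over all pairwise closed-interval overlaps."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            if max(s1, s2) <= min(e1, e2):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestGroupLdWin:
    def test_basic_two_components(self):
        w = _windows([(100, 200), (150, 300), (400, 500)])
        a = _assoc(["m1", "m2", "m3"], pos=[150, 225, 450])
        qtls = group_ld_win(a, w)
        assert [sorted(q.member_ids) for q in qtls] == [["m1", "m2"], ["m3"]]
        assert (qtls[0].lower_bp, qtls[0].upper_bp) == (100, 300)

    def test_transitive_chain(self):
        w = _windows([(1, 10), (9, 20), (19, 30)])
        a = _assoc(["m1", "m2", "m3"], pos=[5, 15, 25])
        qtls = group_ld_win(a, w)
        assert len(qtls) == 1
        assert (qtls[0].lower_bp, qtls[0].upper_bp) == (1, 30)

    def test_zero_width_windows_one_qtl_per_position(self):
        w = _windows([(100, 100), (200, 200), (200, 200), (300, 300)])
        # two markers share position 200 (windows identical -> same QTL)
        w.windows.loc[2, "pos_bp"] = 200
        a = _assoc(["m1", "m2", "m3", "m4"], pos=[100, 200, 200, 300])
        assert len(group_ld_win(a, w)) == 3

    def test_order_invariance_and_idempotence(self):
        w = _windows([(10, 30), (25, 50), (100, 120), (115, 130), (300, 310)])
        ids = [f"m{k}" for k in range(1, 6)]
        a = _assoc(ids, pos=[20, 40, 110, 120, 305])
        q1 = group_ld_win(a, w)
        q2 = group_ld_win(a.iloc[::-1], w)
        assert [q.member_ids for q in q1] == [q.member_ids for q in q2]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_windows_match_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        s = rng.integers(1, 10_000, n)
        e = s + rng.integers(0, 500, n)
        w = _windows(list(zip(s, e)))
        a = _assoc([f"m{k+1}" for k in range(n)], pos=list((s + e) // 2))
        got = sorted(
            tuple(sorted(int(m[1:]) - 1 for m in q.member_ids))
            for q in group_ld_win(a, w)
        )
        assert got == _brute_force_components(list(zip(s, e)))


class TestGroupLdAdj:
    def _ld_fn(self, table):
        return lambda a, b: table.get((a, b), table.get((b, a), np.nan))

    def test_split_pattern(self):
        a = _assoc(["m1", "m2", "m3", "m4"], pos=[100, 200, 300, 400])
        ld = self._ld_fn({("m1", "m2"): 0.6, ("m2", "m3"): 0.4, ("m3", "m4"): 0.7})
        qtls = group_ld_adj(a, ld)
        assert [q.member_ids for q in qtls] == [["m1", "m2"], ["m3", "m4"]]

    def test_all_connected(self):
        a = _assoc(["m1", "m2", "m3"], pos=[1, 2, 3])
        qtls = group_ld_adj(a, lambda x, y: 0.9)
        assert len(qtls) == 1

    def test_exactly_half_splits(self):
        a = _assoc(["m1", "m2"], pos=[1, 2])
        assert len(group_ld_adj(a, lambda x, y: 0.5)) == 2

    def test_undefined_ld_breaks_with_warning(self):
        a = _assoc(["m1", "m2"], pos=[1, 2])
        with pytest.warns(UserWarning, match="undefined"):
            qtls = group_ld_adj(a, lambda x, y: np.nan)
        assert len(qtls) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_random_sequences_match_brute_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ids = [f"m{k+1}" for k in range(n)]
        vals = rng.uniform(0, 1, n - 1)
        table = {(ids[k], ids[k + 1]): vals[k] for k in range(n - 1)}
        a = _assoc(ids, pos=list(range(100, 100 * n + 1, 100)))
        qtls = group_ld_adj(a, self._ld_fn(table))
        # brute scan: count breaks where adjacent LD <= 0.5
        expect = 1 + int((vals <= 0.5).sum())
        assert len(qtls) == expect


class TestSummarize:
    def test_env_counting_and_tie_rule(self):
        w = _windows([(100, 200), (150, 260)])
        frames = [
            _assoc(["m1", "m2"], pos=[150, 210], neglog10p=[7.0, 7.0], env="e1"),
            _assoc(["m1", "m2"], pos=[150, 210], neglog10p=[4.0, 6.0], env="e2"),
            _assoc(["m1", "m2"], pos=[150, 210], neglog10p=[2.0, 5.5], env="e3"),
        ]
        a = pd.concat(frames, ignore_index=True)
        qtls = group_ld_win(a, w)
        assert len(qtls) == 1
        summary = summarize_qtl(qtls, a)
        row = summary.iloc[0]
        assert row["n_diff_env"] == 3
        # tie at 7.0 in e1: the lower-position marker wins
        assert row["pos_max"] == 150 and row["env_max"] == "e1"

    def test_peak_r2_against_phenotype(self, sim_panel, sim_phenotypes,
                                       sim_truth, sim_kchr):
        from ldgwas.gwas import scan
        frames = [
            scan(sim_panel, sim_phenotypes.vector("trait1", e), sim_kchr,
                 trait="trait1", environment=e)
            for e in sim_phenotypes.environments("trait1")
        ]
        a = pd.concat(frames, ignore_index=True)
        sig = a[a["neglog10p"] > 5.0]
        if len(sig) == 0:
            pytest.skip("no significant markers at this seed")
        w = _windows([(p - 50_000, p + 50_000) for p in sig["pos_bp"]])
        w.windows["marker_id"] = sig["marker_id"].to_numpy()
        w.windows["chrom"] = sig["chrom"].to_numpy()
        w.windows["pos_bp"] = sig["pos_bp"].to_numpy()
        qtls = group_ld_win(a, w)
        summary = summarize_qtl(qtls, a, sim_panel, sim_phenotypes)
        assert (summary["r2"].dropna() >= 0).all()
        assert (summary["r2"].dropna() <= 1).all()


class TestColocalize:
    def _qtl(self, trait, chrom, lo, hi, qid="q"):
        from ldgwas.qtl import QTL
        return QTL(qid, trait, "LD_WIN", chrom, lo, hi, ["m"])

    def test_identical_and_disjoint(self):
        out = colocalize({
            "t1": [self._qtl("t1", 1, 100, 200)],
            "t2": [self._qtl("t2", 1, 100, 200)],
            "t3": [self._qtl("t3", 2, 100, 200)],
        })
        assert set(out.loc[out["trait"] == "t1", "class"]) == {"shared"}
        assert set(out.loc[out["trait"] == "t3", "class"]) == {"trait_specific"}

    def test_nested_shared_and_random_oracle(self):
        rng = np.random.default_rng(0)
        qa = [self._qtl("a", 1, s, s + w, f"a{k}") for k, (s, w) in
              enumerate(zip(rng.integers(1, 5000, 50), rng.integers(0, 400, 50)))]
        qb = [self._qtl("b", 1, s, s + w, f"b{k}") for k, (s, w) in
              enumerate(zip(rng.integers(1, 5000, 50), rng.integers(0, 400, 50)))]
        out = colocalize({"a": qa, "b": qb})
        for q in qa:
            expect = any(max(q.lower_bp, p.lower_bp) <= min(q.upper_bp, p.upper_bp)
                         for p in qb)
            got = out.loc[out["qtl_id"] == q.qtl_id, "class"].iloc[0]
            assert (got == "shared") == expect


class TestStability:
    def test_counts(self):
        summary = pd.DataFrame({
            "n_diff_env": [1] * 8 + [2, 3],
            "region_class": ["HIGH"] * 10,
        })
        out = stability_table(summary)
        assert out["pct_multi_env"] == pytest.approx(20.0)
        assert out["pct_high_rec"] == pytest.approx(100.0)


class TestLocalHaplotypes:
    def test_two_duplicated_groups_perfect_split(self):
        h1 = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        h2 = np.array([1, 0, 1, 0, 0, 1], dtype=float)
        dose = np.vstack([h1] * 6 + [h2] * 6)
        G = make_panel(dose, pos=[1000 * (k + 1) for k in range(6)])
        labels, order, sel = local_haplotypes(G, 1, 1, 10_000, k=2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_k_one_single_cluster(self):
        dose = np.random.default_rng(0).choice([0.0, 1.0], size=(8, 5))
        G = make_panel(dose)
        labels, _, _ = local_haplotypes(G, 1, 1, 10_000, k=1)
        assert set(labels) == {1}

    def test_k_exceeds_lines_rejected(self):
        G = make_panel(np.zeros((3, 4)) + np.eye(3, 4))
        with pytest.raises(ValueError, match="exceeds"):
            local_haplotypes(G, 1, 1, 10_000, k=5)

    def test_three_noisy_groups_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.choice([0.0, 1.0], size=(3, 40))
        truth = np.repeat([0, 1, 2], 15)
        dose = base[truth]
        noise = rng.random(dose.shape) < 0.02
        dose = np.where(noise, 1 - dose, dose)
        G = make_panel(dose, pos=[500 * (k + 1) for k in range(40)])
        labels, _, _ = local_haplotypes(G, 1, 1, 100_000, k=3)
        assert adjusted_rand_score(truth, labels) > 0.9
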