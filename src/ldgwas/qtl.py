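"""Grouping significant SNPs into QTLs, summaries, colocalization, haplotypes.

Two LD-driven grouping rules:

* ``LD_win`` — significant SNPs whose LD windows (at r2K = 0.1) overlap
  belong to the same QTL; the relation is closed transitively, and the QTL
  limits are the union span of member windows.
* ``LD_adj`` — consecutive significant SNPs (physical order) stay in the
  same QTL while the r2K between adjacent SNPs exceeds 0.5; a value <= 0.5
  (or an undefined one) splits.

Significant SNPs from all environments of a trait are pooled before
grouping, so a QTL is one entity across environments; per-environment
detection is recovered in the summary (NbDiffEnv, EnvMax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import GenotypeMatrix, RecombProfile
from .decay import LDWindowTable


@dataclass
class QTL:
    qtl_id: str
    trait: str
    method: str  # LD_WIN | LD_ADJ
    chrom: int
    lower_bp: int
    upper_bp: int
    member_ids: list[str]
    peak_id: str = ""
    peak_pos_bp: int = 0
    peak_neglog10p: float = np.nan
    peak_effect: float = np.nan
    peak_maf: float = np.nan
    peak_r2: float = np.nan
    env_max: str = ""
    n_diff_env: int = 0
    region_class: str = ""
    environments: list[str] = field(default_factory=list)


def _significant(assoc: pd.DataFrame, threshold: float) -> pd.DataFrame:
    return assoc[assoc["neglog10p"] > threshold]


def group_ld_win(
    assoc: pd.DataFrame,
    windows: LDWindowTable,
    threshold: float = 5.0,
    trait: str | None = None,
) -> list[QTL]:
    """Connected components of the LD-window overlap graph of significant SNPs.

    ``assoc`` is a scan output (possibly pooled over environments); rows
    with neglog10p > threshold are grouped.  Closed intervals overlap iff
    max(starts) <= min(ends); components are found by a sorted sweep, which
    equals the transitive closure of pairwise overlap.
    """
    sig = _significant(assoc, threshold)
    trait = trait or (sig["trait"].iloc[0] if len(sig) else "trait")
    ids = sig["marker_id"].unique()
    w = windows.windows.set_index("marker_id")
    missing = [i for i in ids if i not in w.index]
    if missing:
        raise KeyError(f"significant markers without LD windows: {missing[:5]}")
    sub = w.loc[ids].reset_index()
    qtls: list[QTL] = []
    for c, grp in sub.groupby("chrom", sort=True):
        grp = grp.sort_values(["start_bp", "pos_bp"], kind="stable")
        cur: list[int] = []
        cur_end = -np.inf
        for row in grp.itertuples():
            if cur and row.start_bp > cur_end:
                qtls.append(_make_qtl(grp.loc[cur], trait, "LD_WIN", int(c)))
                cur = []
                cur_end = -np.inf
            cur.append(row.Index)
            cur_end = max(cur_end, row.end_bp)
        if cur:
            qtls.append(_make_qtl(grp.loc[cur], trait, "LD_WIN", int(c)))
    return _assign_ids(qtls, trait)


def _make_qtl(members: pd.DataFrame, trait: str, method: str, chrom: int) -> QTL:
    members = members.sort_values("pos_bp", kind="stable")
    return QTL(
        qtl_id="",
        trait=trait,
        method=method,
        chrom=chrom,
        lower_bp=int(members["start_bp"].min()),
        upper_bp=int(members["end_bp"].max()),
        member_ids=members["marker_id"].tolist(),
    )


def _assign_ids(qtls: list[QTL], trait: str) -> list[QTL]:
    qtls.sort(key=lambda q: (q.chrom, q.lower_bp, q.upper_bp))
    for k, q in enumerate(qtls, start=1):
        q.qtl_id = f"{trait}_{k}"
    return qtls


def group_ld_adj(
    assoc: pd.DataFrame,
    ld_fn,
    threshold_p: float = 5.0,
    ld_threshold: float = 0.5,
    trait: str | None = None,
) -> list[QTL]:
    """Split position-sorted significant SNPs where adjacent r2K <= 0.5.

    ``ld_fn(marker_id_a, marker_id_b) -> float`` supplies the corrected LD;
    an undefined (NaN) value is treated as a break.  Grouping is per
    chromosome; QTL limits are the member positions' span.
    """
    sig = _significant(assoc, threshold_p)
    trait = trait or (sig["trait"].iloc[0] if len(sig) else "trait")
    per_marker = (
        sig.groupby("marker_id", sort=False)
        .agg(chrom=("chrom", "first"), pos_bp=("pos_bp", "first"))
        .reset_index()
    )
    qtls: list[QTL] = []
    for c, grp in per_marker.groupby("chrom", sort=True):
        grp = grp.sort_values("pos_bp", kind="stable").reset_index(drop=True)
        runs: list[list[int]] = [[0]] if len(grp) else []
        for k in range(1, len(grp)):
            r2k = ld_fn(grp["marker_id"][k - 1], grp["marker_id"][k])
            if np.isnan(r2k):
                warnings.warn(
                    f"undefined LD between {grp['marker_id'][k-1]} and "
                    f"{grp['marker_id'][k]}: treated as a break"
                )
            if not np.isnan(r2k) and r2k > ld_threshold:
                runs[-1].append(k)
            else:
                runs.append([k])
        for run in runs:
            mem = grp.loc[run]
            qtls.append(
                QTL(
                    qtl_id="",
                    trait=trait,
                    method="LD_ADJ",
                    chrom=int(c),
                    lower_bp=int(mem["pos_bp"].min()),
                    upper_bp=int(mem["pos_bp"].max()),
                    member_ids=mem["marker_id"].tolist(),
                )
            )
    return _assign_ids(qtls, trait)


def summarize_qtl(
    qtls: list[QTL],
    assoc: pd.DataFrame,
    G: GenotypeMatrix | None = None,
    phenotypes=None,
    threshold: float = 5.0,
    profile: RecombProfile | None = None,
) -> pd.DataFrame:
    """Fill peak statistics, EnvMax, NbDiffEnv and peak R2 for each QTL.

    Peak = member with the maximum neglog10p over all environments, ties
    broken by genomic order.  NbDiffEnv counts environments where any
    member passes ``threshold``.  R2 is the squared correlation between
    peak doses and the phenotype in EnvMax (when genotypes and phenotypes
    are supplied).
    """
    rows = []
    assoc = assoc.copy()
    for q in qtls:
        mem = assoc[assoc["marker_id"].isin(q.member_ids)]
        mem = mem.sort_values(["neglog10p", "chrom", "pos_bp"],
                              ascending=[False, True, True], kind="stable")
        # tie rule: among rows sharing the max neglog10p, lowest (chrom, pos)
        top_p = mem["neglog10p"].iloc[0]
        peak = (
            mem[mem["neglog10p"] == top_p]
            .sort_values(["chrom", "pos_bp"], kind="stable")
            .iloc[0]
        )
        envs = sorted(mem.loc[mem["neglog10p"] > threshold, "environment"].unique())
        q.peak_id = peak["marker_id"]
        q.peak_pos_bp = int(peak["pos_bp"])
        q.peak_neglog10p = float(peak["neglog10p"])
        q.peak_effect = float(peak["effect"])
        q.peak_maf = float(peak["maf"])
        q.env_max = peak["environment"]
        q.environments = envs
        q.n_diff_env = len(envs)
        if profile is not None:
            q.region_class = str(profile.class_at(q.chrom, q.peak_pos_bp)[0])
        if G is not None and phenotypes is not None:
            col = np.flatnonzero((G.markers["marker_id"] == q.peak_id).to_numpy())
            y = phenotypes.vector(q.trait, q.env_max)
            lines = [l for l in G.line_ids if l in y.index]
            li = [G.line_ids.index(l) for l in lines]
            x = G.dose[li, col[0]]
            yy = y.loc[lines].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(yy)
            if ok.sum() > 2 and np.std(x[ok]) > 0:
                q.peak_r2 = float(np.corrcoef(x[ok], yy[ok])[0, 1] ** 2)
        rows.append(
            (q.qtl_id, q.trait, q.method, q.chrom, q.peak_pos_bp, q.lower_bp,
             q.upper_bp, q.peak_r2, q.peak_effect, q.peak_neglog10p, q.peak_maf,
             q.env_max, q.n_diff_env, q.region_class, len(q.member_ids))
        )
    return pd.DataFrame(
        rows,
        columns=["qtl_id", "trait", "method", "chrom", "pos_max", "lower_limit",
                 "upper_limit", "r2", "effect_max", "neglog10p_max", "maf",
                 "env_max", "n_diff_env", "region_class", "n_members"],
    )


def colocalize(qtls_by_trait: dict[str, list[QTL]]) -> pd.DataFrame:
    """Classify QTLs as trait-specific or shared by physical-interval overlap.

    Two QTLs colocalize iff their closed intervals overlap on the same
    chromosome.  Returns one row per QTL with the set of traits it
    overlaps (including its own) and the derived class.
    """
    rows = []
    traits = sorted(qtls_by_trait)
    for t in traits:
        for q in qtls_by_trait[t]:
            hits = {t}
            for t2 in traits:
                if t2 == t:
                    continue
                for q2 in qtls_by_trait[t2]:
                    if q2.chrom == q.chrom and max(q.lower_bp, q2.lower_bp) <= min(
                        q.upper_bp, q2.upper_bp
                    ):
                        hits.add(t2)
                        break
            rows.append(
                (q.qtl_id, t, q.chrom, q.lower_bp, q.upper_bp,
                 ",".join(sorted(hits)), len(hits),
                 "shared" if len(hits) > 1 else "trait_specific")
            )
    return pd.DataFrame(
        rows, columns=["qtl_id", "trait", "chrom", "lower_bp", "upper_bp",
                       "overlapping_traits", "n_traits", "class"]
    )


def stability_table(summary: pd.DataFrame) -> dict:
    """Counts of QTLs by number of detection environments and region class."""
    by_env = summary["n_diff_env"].value_counts().sort_index().to_dict()
    n = len(summary)
    multi = int((summary["n_diff_env"] >= 2).sum())
    by_class = summary["region_class"].value_counts().to_dict()
    return {
        "n_qtls": n,
        "by_n_env": by_env,
        "n_multi_env": multi,
        "pct_multi_env": 100.0 * multi / n if n else np.nan,
        "by_region_class": by_class,
        "pct_high_rec": 100.0 * by_class.get("HIGH", 0) / n if n else np.nan,
    }


def local_haplotypes(
    G: GenotypeMatrix,
    chrom: int,
    lower_bp: int,
    upper_bp: int,
    k: int,
    min_maf: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cluster lines by local genotype dissimilarity within an interval.

    Pairwise simple mismatch |d_i - d_j| averaged over non-missing markers
    of the interval (MAF-filtered), average-linkage agglomerative
    clustering cut at k clusters.  Returns (cluster labels, dendrogram leaf
    order of lines, marker indices of the interval).
    """
    if k > G.n_lines:
        raise ValueError("k exceeds the number of lines")
    m = G.markers
    sel = np.flatnonzero(
        (m["chrom"] == chrom).to_numpy()
        & (m["pos_bp"].to_numpy() >= lower_bp)
        & (m["pos_bp"].to_numpy() <= upper_bp)
        & (G.maf() >= min_maf)
    )
    if sel.size < 2:
        raise ValueError("fewer than 2 markers in the interval after MAF filter")
    X = G.dose[:, sel]
    obs = ~np.isnan(X)
    Xz = np.nan_to_num(X)
    # mean |d_i - d_j| over jointly observed markers
    npairs = obs.astype(float) @ obs.astype(float).T
    diff = np.abs(Xz[:, None, :] - Xz[None, :, :]) * (obs[:, None, :] & obs[None, :, :])
    D = diff.sum(axis=2) / np.maximum(npairs, 1)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(Z)
    return labels, order, sel
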