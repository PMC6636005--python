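"""Plain and kinship/structure-corrected linkage disequilibrium.

Four pairwise LD statistics on allelic doses:

* ``r2``  — squared Pearson correlation of doses.
* ``r2K`` — squared correlation after whitening both dose vectors by the
  inverse square root of a kinship matrix K (removes LD created by
  relatedness; the statistic addressed by the mixed GWAS model).
* ``r2S`` — squared partial correlation after projecting out admixture
  proportions (and the intercept).
* ``r2KS`` — both corrections: whiten by K^{-1/2}, then project out the
  whitened structure covariates.

The whitening uses a symmetric eigendecomposition with eigenvalues floored
at ``eig_floor``, so K = I recovers the plain r2 exactly and the statistic
is invariant to scaling K by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, RecombProfile
from .popgen import KinshipMatrix, StructureMatrix

EIG_FLOOR = 1e-8

PAIR_COLUMNS = ["i", "j", "marker_i", "marker_j", "chrom", "d_bp", "d_cM"]


def _inv_sqrt(K: np.ndarray, eig_floor: float = EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root of a PSD matrix, eigenvalues floored."""
    vals, vecs = np.linalg.eigh((K + K.T) / 2)
    vals = np.maximum(vals, eig_floor)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _orth(Z: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of Z (rank-deficiency safe)."""
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    return q[:, keep]


def _residual_corr2(u: np.ndarray, v: np.ndarray, Z: np.ndarray) -> float:
    """Squared correlation of u and v after projecting out columns of Z."""
    q = _orth(Z)
    u = u - q @ (q.T @ u)
    v = v - q @ (q.T @ v)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        return np.nan
    return float((u @ v) ** 2 / (nu * nv) ** 2)


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between two dose vectors.

    Pairwise-complete; returns NaN when fewer than 3 complete lines remain
    or either vector is constant on the complete subset.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return np.nan
    return _residual_corr2(x[ok], y[ok], np.ones((int(ok.sum()), 1)))


def ld_corrected(
    x: np.ndarray,
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray | None = None,
    Q: StructureMatrix | np.ndarray | None = None,
    eig_floor: float = EIG_FLOOR,
) -> float:
    """Corrected squared correlation: r2K (K only), r2S (Q only) or r2KS (both).

    Whitening is restricted to the pairwise-complete submatrix of K; the
    intercept (and, if given, the admixture columns) are projected out in
    the whitened space.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return np.nan
    idx = np.flatnonzero(ok)
    u, v = x[idx], y[idx]
    Z = [np.ones(len(idx))]
    if Q is not None:
        Qm = Q.Q if isinstance(Q, StructureMatrix) else np.asarray(Q, float)
        # drop one admixture column: rows sum to 1, the intercept absorbs it
        Z.extend(list(Qm[idx, : max(Qm.shape[1] - 1, 1)].T))
    Z = np.column_stack(Z)
    if K is not None:
        Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        W = _inv_sqrt(Km[np.ix_(idx, idx)], eig_floor)
        u, v, Z = W @ u, W @ v, W @ Z
    return _residual_corr2(u, v, Z)


# ---------------------------------------------------------------------------
# Bulk computation
# ---------------------------------------------------------------------------

def whitened_doses(
    G: GenotypeMatrix,
    K: KinshipMatrix | None = None,
    Q: StructureMatrix | None = None,
    eig_floor: float = EIG_FLOOR,
) -> np.ndarray:
    """Residualized (and optionally whitened) standardized dose matrix.

    Missing doses are replaced by the marker mean before whitening (the
    scalar ops offer exact pairwise-complete handling; for bulk work on
    hundreds of thousands of pairs the mean-impute route is used).  Columns
    are scaled to unit norm, so r2 between markers a, b is simply the
    squared dot product of columns a and b.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(G.dose, axis=0)
    X = np.where(np.isnan(G.dose), mean, G.dose)
    Z = [np.ones(G.n_lines)]
    if Q is not None:
        Z.extend(list(Q.Q[:, : max(Q.Q.shape[1] - 1, 1)].T))
    Z = np.column_stack(Z)
    if K is not None:
        W = _inv_sqrt(K.matrix, eig_floor)
        X, Z = W @ X, W @ Z
    q = _orth(Z)
    X = X - q @ (q.T @ X)
    norms = np.linalg.norm(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(norms > 1e-12, X / norms, np.nan)
    return X


def compute_pair_ld(
    G: GenotypeMatrix,
    pairs: pd.DataFrame,
    K: KinshipMatrix | dict[int, KinshipMatrix] | None = None,
    Q: StructureMatrix | None = None,
    column: str = "r2K",
) -> pd.DataFrame:
    """Attach an LD statistic to a pair table produced by sample_locus_pairs.

    ``K`` may be a single kinship or a dict chrom -> leave-that-chromosome-out
    kinship, in which case each pair uses the kinship excluding its own
    chromosome (the statistic seen by the GWAS mixed model).
    """
    out = pairs.reset_index(drop=True).copy()
    stat = np.empty(len(out))
    if isinstance(K, dict):
        for c, sub in out.groupby("chrom"):
            X = whitened_doses(G, K[int(c)], Q)
            ii = sub["i"].to_numpy()
            jj = sub["j"].to_numpy()
            stat[sub.index.to_numpy()] = np.einsum("ij,ij->j", X[:, ii], X[:, jj]) ** 2
    else:
        X = whitened_doses(G, K, Q)
        ii = out["i"].to_numpy()
        jj = out["j"].to_numpy()
        stat = np.einsum("ij,ij->j", X[:, ii], X[:, jj]) ** 2
    out[column] = stat
    return out


def sample_locus_pairs(
    G: GenotypeMatrix,
    profile: RecombProfile,
    region_class: str,
    n_pairs: int = 500_000,
    n_sets: int = 100,
    max_dist_cM: float = 1.0,
    seed: int = 0,
    chrom: int | None = None,
) -> list[pd.DataFrame]:
    """Random sets of same-chromosome locus pairs within ``max_dist_cM``.

    Pairs are drawn uniformly without replacement from all eligible pairs
    whose two markers both fall in windows of ``region_class``; the MAF
    filter is assumed already applied.  Each returned set has columns
    ``i, j, marker_i, marker_j, chrom, d_bp, d_cM``.
    """
    m = G.markers
    eligible_left, eligible_right = [], []
    chroms = [chrom] if chrom is not None else G.chroms
    for c in chroms:
        on = np.flatnonzero((m["chrom"] == c).to_numpy())
        if on.size == 0:
            continue
        cls = profile.class_at(c, m["pos_bp"].to_numpy()[on])
        on = on[cls == region_class]
        cm = m["pos_cM"].to_numpy()[on]
        # two-pointer enumeration of pairs within max_dist_cM (cm sorted)
        right = np.searchsorted(cm, cm + max_dist_cM, side="right")
        for a in range(len(on)):
            b = np.arange(a + 1, right[a])
            if b.size:
                eligible_left.append(np.full(b.size, on[a]))
                eligible_right.append(on[b])
    if not eligible_left:
        return [pd.DataFrame(columns=PAIR_COLUMNS) for _ in range(n_sets)]
    left = np.concatenate(eligible_left)
    right = np.concatenate(eligible_right)
    n_eligible = len(left)
    take = min(n_pairs, n_eligible)
    if take < n_pairs:
        warnings.warn(
            f"only {n_eligible} eligible pairs (< requested {n_pairs}); sampling all"
        )
    rng = np.random.default_rng(seed)
    pos = m["pos_bp"].to_numpy()
    cm_all = m["pos_cM"].to_numpy()
    chrom_all = m["chrom"].to_numpy()
    ids = m["marker_id"].to_numpy()
    sets = []
    for _ in range(n_sets):
        sel = rng.choice(n_eligible, size=take, replace=False)
        i, j = left[sel], right[sel]
        sets.append(
            pd.DataFrame(
                {
                    "i": i,
                    "j": j,
                    "marker_i": ids[i],
                    "marker_j": ids[j],
                    "chrom": chrom_all[i],
                    "d_bp": np.abs(pos[i] - pos[j]),
                    "d_cM": np.abs(cm_all[i] - cm_all[j]),
                }
            )
        )
    return sets


def ld_matrix(
    G: GenotypeMatrix,
    marker_index: np.ndarray | list[int],
    K: KinshipMatrix | None = None,
    Q: StructureMatrix | None = None,
    allow_large: bool = False,
) -> np.ndarray:
    """Symmetric matrix of the chosen LD statistic over a marker subset.

    Plain r2 when K and Q are None, r2K/r2S/r2KS otherwise; diagonal 1.
    Requires ``allow_large=True`` beyond 2,000 markers (quadratic cost).
    """
    marker_index = np.asarray(marker_index)
    if len(marker_index) > 2000 and not allow_large:
        raise ValueError("more than 2,000 markers: pass allow_large=True")
    X = whitened_doses(G, K, Q)[:, marker_index]
    M = (X.T @ X) ** 2
    np.fill_diagonal(M, 1.0)
    return M
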