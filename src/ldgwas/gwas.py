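"""Mixed-model association scan with leave-one-chromosome-out kinship.

For a marker on chromosome c the model is

    y = mu + x b + g + e,   g ~ N(0, sg2 * K_chr(c)),   e ~ N(0, se2 * I)

The variance ratio delta = se2/sg2 is REML-estimated once per chromosome
under the null (no marker) via the spectral decomposition of K_chr(c); each
marker is then tested by generalized least squares with the total variance
re-profiled per marker, giving an F(1, n-p) test of b = 0.  With K = I this
reduces exactly to the ordinary least-squares F-test.

Multiple testing uses the eigenvalue-based effective number of independent
tests (simpleM): per block of consecutive markers, the number of leading
eigenvalues of the marker correlation matrix needed to explain 99.5% of its
trace, summed over blocks, enters the Bonferroni formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .core import GenotypeMatrix
from .popgen import KinshipMatrix


@dataclass
class ThresholdReport:
    M_markers: int
    M_eff: int
    alpha: float
    bonferroni_neglog10: float
    fixed_thresholds: tuple[float, float] = (5.0, 8.0)


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

def _reml_delta(yr: np.ndarray, Xr: np.ndarray, s: np.ndarray) -> float:
    """Profile-REML estimate of delta = se2/sg2 on rotated data.

    ``yr`` and ``Xr`` are U'y and U'X for the eigendecomposition
    K = U diag(s) U'; the variance of rotated residual i is
    sg2 * (s_i + delta).
    """
    n, p = Xr.shape

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (s + delta)
        Xw = Xr * w[:, None]
        XtX = Xr.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yr)
        r = yr - Xr @ beta
        rss = float(np.sum(w * r * r))
        sg2 = rss / (n - p)
        _, ld1 = np.linalg.slogdet(XtX)
        return (
            (n - p) * np.log(sg2)
            + np.sum(np.log(s + delta))
            + ld1
            + (n - p)
        )

    # coarse grid then local refinement (the profile is often multimodal-free
    # but flat; the grid protects the bracket)
    grid = np.linspace(-8, 8, 33)
    vals = [neg_reml(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        neg_reml, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


def scan(
    G: GenotypeMatrix,
    y: pd.Series,
    K_chr: dict[int, KinshipMatrix] | KinshipMatrix,
    covariates: np.ndarray | None = None,
    trait: str = "trait",
    environment: str = "env",
    min_maf: float = 0.05,
    eig_floor: float = 1e-6,
) -> pd.DataFrame:
    """Single-trait single-environment mixed-model scan.

    ``y`` is indexed by line id; lines missing a phenotype are dropped.
    ``K_chr`` maps chromosome -> kinship excluding it (a single kinship is
    used for every chromosome if given directly).  Returns one row per
    tested marker with effect (allele coded 1), p_value, neglog10p, MAF and
    the number of lines used.
    """
    lines = [l for l in G.line_ids if l in y.index and np.isfinite(y[l])]
    if len(lines) < 10:
        raise ValueError("fewer than 10 phenotyped lines")
    li = np.array([G.line_ids.index(l) for l in lines])
    yv = y.loc[lines].to_numpy(float)
    maf = G.maf()
    rows = []
    for c in G.chroms:
        K = K_chr[c] if isinstance(K_chr, dict) else K_chr
        Km = K.matrix[np.ix_(li, li)]
        s, U = np.linalg.eigh((Km + Km.T) / 2)
        if s.min() < -1e-6:
            Km = Km + (eig_floor - s.min()) * np.eye(len(li))
            s, U = np.linalg.eigh(Km)
        s = np.maximum(s, eig_floor)
        X0 = np.ones((len(li), 1))
        if covariates is not None:
            X0 = np.column_stack([X0, np.asarray(covariates)[li]])
        yr = U.T @ yv
        X0r = U.T @ X0
        delta = _reml_delta(yr, X0r, s)
        w = 1.0 / (s + delta)

        on = np.flatnonzero((G.markers["chrom"] == c).to_numpy() & (maf >= min_maf))
        doses = G.dose[np.ix_(li, on)]
        complete = ~np.isnan(doses).any(axis=0)

        # fast path: rotate all complete markers at once
        comp = np.flatnonzero(complete)
        if comp.size:
            Xr = U.T @ doses[:, comp]
            rows.extend(
                _gls_batch(yr, X0r, Xr, w, on[comp], G, maf, trait, environment, len(li))
            )
        # slow path: markers with missing doses, lines dropped marker-wise
        for k in np.flatnonzero(~complete):
            ok = ~np.isnan(doses[:, k])
            if ok.sum() < 10 or np.nanstd(doses[:, k]) == 0:
                continue
            Ks = Km[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))]
            ss, Us = np.linalg.eigh((Ks + Ks.T) / 2)
            ss = np.maximum(ss, eig_floor)
            ws = 1.0 / (ss + delta)
            yrs = Us.T @ yv[ok]
            X0s = Us.T @ X0[ok]
            xrs = Us.T @ doses[ok, k]
            rows.extend(
                _gls_batch(yrs, X0s, xrs[:, None], ws, on[[k]], G, maf,
                           trait, environment, int(ok.sum()))
            )
    out = pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "pos_bp", "trait", "environment",
                 "effect", "p_value", "neglog10p", "maf", "n_used"],
    )
    return out.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)


def _gls_batch(yr, X0r, Xr, w, marker_idx, G, maf, trait, environment, n_used):
    """Weighted LS test of each column of Xr added to the null design X0r."""
    n, p0 = X0r.shape
    p = p0 + 1
    rows = []
    sw = np.sqrt(w)
    yw = yr * sw
    X0w = X0r * sw[:, None]
    Q0, _ = np.linalg.qr(X0w)
    y_res = yw - Q0 @ (Q0.T @ yw)
    for col, mi in enumerate(np.atleast_1d(marker_idx)):
        xw = Xr[:, col] * sw
        x_res = xw - Q0 @ (Q0.T @ xw)
        xtx = float(x_res @ x_res)
        if xtx < 1e-12:
            continue
        b = float(x_res @ y_res) / xtx
        rss = float(y_res @ y_res) - b * b * xtx
        dof = n - p
        if dof <= 0 or rss <= 0:
            continue
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / xtx)
        F = (b / se) ** 2
        pval = float(stats.f.sf(F, 1, dof))
        pval = max(pval, 1e-300)
        m = G.markers.iloc[mi]
        rows.append(
            (m["marker_id"], int(m["chrom"]), int(m["pos_bp"]), trait, environment,
             b, pval, -np.log10(pval), float(maf[mi]), n_used)
        )
    return rows


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def effective_tests_gao(
    G: GenotypeMatrix,
    explained_variance: float = 0.995,
    block_size: int = 200,
) -> int:
    """simpleM effective number of independent tests.

    Markers are processed in consecutive blocks (within the sorted order);
    for each block, count the leading eigenvalues of the marker correlation
    matrix needed to reach ``explained_variance`` of the trace, and sum.
    """
    M = G.n_markers
    if M == 0:
        return 0
    block_size = min(block_size, M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(G.dose, axis=0)
    X = np.where(np.isnan(G.dose), mean, G.dose)
    m_eff = 0
    for start in range(0, M, block_size):
        B = X[:, start : start + block_size]
        sd = B.std(axis=0)
        keep = sd > 0
        if not keep.any():
            continue
        Bz = (B[:, keep] - B[:, keep].mean(0)) / sd[keep]
        corr = Bz.T @ Bz / Bz.shape[0]
        vals = np.linalg.eigvalsh(corr)[::-1]
        vals = np.clip(vals, 0, None)
        cum = np.cumsum(vals) / vals.sum()
        m_eff += int(np.searchsorted(cum, explained_variance - 1e-12) + 1)
    return m_eff


def bonferroni_threshold(M_eff: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected per-test level alpha / M_eff."""
    if M_eff < 1:
        raise ValueError("M_eff must be >= 1")
    return float(-np.log10(alpha / M_eff))


def threshold_report(
    G: GenotypeMatrix, alpha: float = 0.05, explained_variance: float = 0.995,
    block_size: int = 200,
) -> ThresholdReport:
    m_eff = effective_tests_gao(G, explained_variance, block_size)
    return ThresholdReport(
        M_markers=G.n_markers,
        M_eff=m_eff,
        alpha=alpha,
        bonferroni_neglog10=bonferroni_threshold(m_eff, alpha),
    )


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def expected_false_positives(
    M_markers: int, n_situations: int, p_threshold: float,
    observed: int | None = None,
) -> dict:
    """Expected false positives under the null and the implied FDR.

    expected = M_markers * n_situations * p_threshold (also reported
    rounded half-up); FDR% = rounded expected / observed * 100 when an
    observed association count is given.
    """
    if min(M_markers, n_situations) <= 0 or p_threshold <= 0:
        raise ValueError("inputs must be positive")
    exp_raw = M_markers * n_situations * p_threshold
    out = {"expected": exp_raw, "expected_rounded": round_half_up(exp_raw)}
    if observed is not None:
        if observed == 0:
            out["fdr_percent"] = np.nan
            out["fdr_undefined"] = True
        else:
            out["fdr_percent"] = out["expected_rounded"] / observed * 100.0
    return out
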