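"""Hill-Weir LD decay fitting, LD extents, per-SNP LD windows and coverage.

The expected squared correlation between two loci separated by a composite
recombination parameter C (proportional to distance) in a sample of n
gametes follows Hill & Weir (1988):

    E(r2 | C) = [(10 + C) / ((2 + C)(11 + C))]
                * [1 + ((3 + C)(12 + 12 C + C^2)) / (n (2 + C)(11 + C))]

We fit the single slope ``beta`` in ``C = beta * d`` by nonlinear least
squares on observed (distance, r2K) pairs, separately per chromosome and
recombination class, on genetic distance (cM) in high-recombination
regions and physical distance (bp) in low-recombination regions.  The LD
extent at a target r2 level is the distance where the fitted curve crosses
it; a half-window of that extent around each SNP defines its LD window,
whose unions give genome coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .core import GeneticMap, GenotypeMatrix, RecombProfile, project_position

EXTENT_THRESHOLDS = (0.1, 0.2, 0.4)
INF_EXTENT = np.inf


def hill_weir_expectation(C: np.ndarray | float, n: int) -> np.ndarray | float:
    """Expected r2 given composite parameter C and sample size n."""
    C = np.asarray(C, dtype=float)
    a = (10 + C) / ((2 + C) * (11 + C))
    b = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    out = a * b
    return float(out) if out.ndim == 0 else out


@dataclass
class LDDecayFit:
    chrom: int | str
    region_class: str  # HIGH | LOW
    distance_scale: str  # "cM" | "bp"
    beta: float  # slope of C = beta * d
    n_sample: int
    sse: float
    n_pairs: int = 0
    converged: bool = True
    extents: dict[float, float] = field(default_factory=dict)

    def expectation(self, d: np.ndarray | float) -> np.ndarray | float:
        return hill_weir_expectation(self.beta * np.asarray(d, float), self.n_sample)


def fit_hill_weir(
    pairs: pd.DataFrame,
    distance_scale: str,
    n_sample: int,
    stat_column: str = "r2K",
    max_dist: float | None = None,
) -> LDDecayFit:
    """Least-squares Hill-Weir fit of beta on a pair set.

    ``distance_scale`` selects the ``d_cM`` or ``d_bp`` column.  Pairs at
    exactly zero distance (duplicate positions across technologies) and
    pairs with an undefined statistic are excluded.
    """
    dcol = {"cM": "d_cM", "bp": "d_bp"}[distance_scale]
    d = pairs[dcol].to_numpy(float)
    r2 = pairs[stat_column].to_numpy(float)
    ok = np.isfinite(d) & np.isfinite(r2) & (d > 0)
    if max_dist is not None:
        ok &= d <= max_dist
    d, r2 = d[ok], r2[ok]
    if len(d) < 100:
        raise ValueError(f"only {len(d)} usable pairs (need >= 100)")

    # initial slope: C ~ 1 at the distance where mean r2 halves
    med = float(np.median(d))
    beta0 = 1.0 / med if med > 0 else 1.0

    def resid(logbeta: np.ndarray) -> np.ndarray:
        return hill_weir_expectation(np.exp(logbeta[0]) * d, n_sample) - r2

    sol = least_squares(resid, x0=[np.log(beta0)], method="lm", max_nfev=200)
    beta = float(np.exp(sol.x[0]))
    fit = LDDecayFit(
        chrom=pairs["chrom"].iloc[0] if pairs["chrom"].nunique() == 1 else "all",
        region_class="",
        distance_scale=distance_scale,
        beta=beta,
        n_sample=n_sample,
        sse=float(np.sum(sol.fun**2)),
        n_pairs=len(d),
        converged=bool(sol.success),
    )
    if not sol.success:
        raise RuntimeError(f"Hill-Weir fit did not converge (best beta {beta:.4g})")
    upper = 10.0 * float(np.quantile(d, 0.99))
    fit.extents = {t: ld_extent(fit, t, upper_bracket=upper) for t in EXTENT_THRESHOLDS}
    return fit


def ld_extent(fit: LDDecayFit, threshold: float, upper_bracket: float | None = None) -> float:
    """Distance where the fitted decay curve reaches ``threshold``.

    Returns 0 when the curve starts below the threshold, ``inf`` when its
    asymptote stays above (flagged sentinel).
    """
    at0 = hill_weir_expectation(0.0, fit.n_sample)
    if at0 <= threshold:
        return 0.0
    hi = upper_bracket or 1.0 / max(fit.beta, 1e-300) * 1e6
    while hill_weir_expectation(fit.beta * hi, fit.n_sample) > threshold:
        hi *= 10
        if fit.beta * hi > 1e15:
            return INF_EXTENT
    return float(
        brentq(
            lambda x: hill_weir_expectation(fit.beta * x, fit.n_sample) - threshold,
            0.0,
            hi,
            xtol=1e-12,
            rtol=1e-12,
        )
    )


@dataclass
class LDWindowTable:
    """Closed physical LD windows [start_bp, end_bp] around markers."""

    windows: pd.DataFrame  # marker_id, chrom, pos_bp, start_bp, end_bp, region_class, flagged
    threshold: float = 0.1

    def to_bed(self, path) -> None:
        """BED export (the one place 0-based half-open coordinates appear)."""
        bed = self.windows[["chrom", "start_bp", "end_bp", "marker_id"]].copy()
        bed["start_bp"] -= 1
        bed.to_csv(path, sep="\t", header=False, index=False)


def build_ld_windows(
    G: GenotypeMatrix,
    fits: dict[tuple, LDDecayFit],
    profile: RecombProfile,
    gmap: GeneticMap,
    threshold: float = 0.1,
    min_maf: float = 0.05,
) -> LDWindowTable:
    """Per-SNP LD windows from the decay fits.

    ``fits`` maps (chrom, region_class) -> fit; LOW-region markers get a
    physical half-window equal to the bp extent, HIGH-region markers a
    genetic half-window (cM extent) projected back to bp through the map.
    Windows are clipped to [1, chrom_length]; an infinite extent spans the
    marker's contiguous region-class segment and is flagged.
    """
    maf = G.maf()
    rows = []
    for c in G.chroms:
        length = gmap.chrom_length_bp[c]
        on = np.flatnonzero((G.markers["chrom"] == c).to_numpy() & (maf >= min_maf))
        if on.size == 0:
            continue
        pos = G.markers["pos_bp"].to_numpy()[on]
        cls = profile.class_at(c, pos)
        segs = profile.segments(c)
        for cl in ("LOW", "HIGH"):
            sub = on[cls == cl]
            if sub.size == 0:
                continue
            fit = fits[(c, cl)]
            ext = fit.extents.get(threshold)
            if ext is None:
                ext = ld_extent(fit, threshold)
            p = G.markers["pos_bp"].to_numpy()[sub]
            if np.isinf(ext):
                # span the marker's own region-class segment
                seg = segs[segs["region_class"] == cl]
                si = np.clip(
                    np.searchsorted(seg["start_bp"].to_numpy(), p, side="right") - 1,
                    0, len(seg) - 1,
                )
                lo = seg["start_bp"].to_numpy()[si]
                hi = seg["end_bp"].to_numpy()[si]
                flagged = np.ones(len(sub), bool)
            elif cl == "LOW":
                lo = np.maximum(np.round(p - ext), 1)
                hi = np.minimum(np.round(p + ext), length)
                flagged = np.zeros(len(sub), bool)
            else:  # HIGH: genetic extent projected to bp
                cm = project_position(gmap, c, p.astype(float), "bp_to_cM")
                lo = project_position(gmap, c, cm - ext, "cM_to_bp")
                hi = project_position(gmap, c, cm + ext, "cM_to_bp")
                lo = np.maximum(np.round(lo), 1)
                hi = np.minimum(np.round(hi), length)
                flagged = np.zeros(len(sub), bool)
            ids = G.markers["marker_id"].to_numpy()[sub]
            for mid, pp, l, h, fl in zip(ids, p, lo, hi, flagged):
                rows.append((mid, c, int(pp), int(l), int(h), cl, bool(fl)))
    df = pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "pos_bp", "start_bp", "end_bp",
                 "region_class", "flagged"],
    ).sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    return LDWindowTable(df, threshold=threshold)


# ---------------------------------------------------------------------------
# Interval unions and coverage
# ---------------------------------------------------------------------------

def union_intervals(starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Union of closed integer intervals as an array of merged (start, end)."""
    if len(starts) == 0:
        return np.empty((0, 2))
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    merged = [[s[0], e[0]]]
    for a, b in zip(s[1:], e[1:]):
        if a <= merged[-1][1] + 1:  # closed intervals: adjacent integers merge
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray(merged, dtype=float)


def genome_coverage(windows: LDWindowTable, gmap: GeneticMap) -> pd.DataFrame:
    """Fraction of the physical and genetic map covered by LD-window unions.

    One row per chromosome plus a ``total`` row; the genetic fraction
    projects the merged physical bounds to cM before measuring.
    """
    rows = []
    tot_bp = tot_cM = cov_bp = cov_cM = 0.0
    for c in sorted(gmap.chroms):
        w = windows.windows[windows.windows["chrom"] == c]
        merged = union_intervals(w["start_bp"].to_numpy(), w["end_bp"].to_numpy())
        len_bp = float(np.sum(merged[:, 1] - merged[:, 0] + 1)) if len(merged) else 0.0
        if len(merged):
            lo_cm = project_position(gmap, c, merged[:, 0], "bp_to_cM")
            hi_cm = project_position(gmap, c, merged[:, 1], "bp_to_cM")
            len_cm = float(np.sum(hi_cm - lo_cm))
        else:
            len_cm = 0.0
        Lbp = gmap.chrom_length_bp[c]
        LcM = gmap.chrom_length_cM[c]
        rows.append((c, len_bp / Lbp, len_cm / LcM, len_bp, len_cm))
        tot_bp += Lbp
        tot_cM += LcM
        cov_bp += len_bp
        cov_cM += len_cm
    rows.append(("total", cov_bp / tot_bp, cov_cM / tot_cM, cov_bp, cov_cM))
    return pd.DataFrame(
        rows, columns=["chrom", "physical_fraction", "genetic_fraction",
                       "covered_bp", "covered_cM"]
    )


def coverage_profile(
    windows: LDWindowTable,
    gmap: GeneticMap,
    window_sizes_kbp: tuple[int, ...] = (20, 100, 500, 2000),
) -> pd.DataFrame:
    """Covered fraction per non-overlapping interval at several interval sizes."""
    rows = []
    for c in sorted(gmap.chroms):
        w = windows.windows[windows.windows["chrom"] == c]
        merged = union_intervals(w["start_bp"].to_numpy(), w["end_bp"].to_numpy())
        length = gmap.chrom_length_bp[c]
        for size_kbp in window_sizes_kbp:
            size = size_kbp * 1000
            starts = np.arange(1, length + 1, size)
            ends = np.minimum(starts + size - 1, length)
            covered = _covered_in_intervals(merged, starts, ends)
            for s, e, cv in zip(starts, ends, covered):
                rows.append((c, size_kbp, int(s), int(e), cv / (e - s + 1)))
    return pd.DataFrame(
        rows, columns=["chrom", "window_kbp", "start_bp", "end_bp", "covered_fraction"]
    )


def _covered_in_intervals(merged: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Covered bp of each query interval given a merged (disjoint, sorted) union."""
    if len(merged) == 0:
        return np.zeros(len(starts))
    ms, me = merged[:, 0], merged[:, 1]
    cum = np.concatenate([[0.0], np.cumsum(me - ms + 1)])

    def upto(x: np.ndarray) -> np.ndarray:
        """Total covered length in (-inf, x] (closed integer convention)."""
        k = np.searchsorted(ms, x, side="right")
        full = cum[np.maximum(k - 1, 0)]
        partial = np.clip(x - ms[np.maximum(k - 1, 0)] + 1, 0, me[np.maximum(k - 1, 0)] - ms[np.maximum(k - 1, 0)] + 1)
        return np.where(k > 0, full + partial, 0.0)

    return upto(ends) - upto(starts - 1)
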