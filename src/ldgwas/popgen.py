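"""Allele-frequency statistics, kinship estimators and principal coordinates.

Three relatedness estimators are provided for an inbred diversity panel:

* ``K_FREQ`` — allele-frequency-weighted IBD (Astle & Balding style):
  ``K_ij = (1/L) sum_l (G_il - p_l)(G_jl - p_l) / (p_l (1 - p_l))``.
  Sharing a rare allele contributes more than sharing a common one.
* ``IBS`` — proportion of shared alleles (1 equal doses, 0.5 one het,
  0 opposite homozygotes).
* ``K_CHR`` — K_FREQ computed on every chromosome except one, used as the
  random-effect covariance when scanning markers of the excluded
  chromosome so the tested locus does not absorb its own effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix


@dataclass
class KinshipMatrix:
    matrix: np.ndarray  # (N, N)
    estimator: str  # K_FREQ | IBS | K_CHR
    line_ids: list[str]
    excluded_chrom: int | None = None
    n_markers_used: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class StructureMatrix:
    """Admixture proportions: rows are lines, columns ancestral groups."""

    Q: np.ndarray  # (N, N_Q)
    line_ids: list[str]
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if np.any(self.Q < -1e-9) or np.any(self.Q > 1 + 1e-9):
            raise ValueError("admixture proportions must lie in [0, 1]")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("admixture rows must sum to 1")
        if not self.group_labels:
            self.group_labels = [f"Q{k + 1}" for k in range(self.Q.shape[1])]


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # (N, k)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    percent_variance: np.ndarray  # per retained axis, over positive eigenvalues
    line_ids: list[str]


# ---------------------------------------------------------------------------

def maf_he(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker allele-1 frequency, MAF and Nei gene diversity He = 2p(1-p).

    Markers with no non-missing call are flagged ``all_missing`` and must be
    excluded downstream.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(G.dose, axis=0)
    all_missing = np.isnan(G.dose).all(axis=0)
    return pd.DataFrame(
        {
            "marker_id": G.markers["marker_id"],
            "p": p,
            "maf": np.minimum(p, 1 - p),
            "he": 2 * p * (1 - p),
            "all_missing": all_missing,
        }
    )


def _polymorphic_mask(G: GenotypeMatrix) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(G.dose, axis=0)
    return np.isfinite(p) & (p > 0) & (p < 1)


def kinship_freq(
    G: GenotypeMatrix,
    marker_mask: np.ndarray | None = None,
    missing_policy: str = "pairwise",
) -> KinshipMatrix:
    """Allele-frequency-weighted IBD kinship.

    Monomorphic markers are excluded (the weight 1/(p(1-p)) diverges).
    ``missing_policy`` is ``pairwise`` (pairwise-complete markers with a
    per-pair denominator) or ``mean`` (missing doses replaced by p_l,
    contributing zero to the numerator).
    """
    mask = _polymorphic_mask(G)
    if marker_mask is not None:
        mask &= marker_mask
    if not mask.any():
        raise ValueError("no polymorphic markers for kinship")
    X = G.dose[:, mask]
    p = np.nanmean(X, axis=0)
    w = np.sqrt(p * (1 - p))
    Z = (X - p) / w  # standardized doses; NaN where missing
    if missing_policy == "mean":
        Znm = np.nan_to_num(Z)
        K = Znm @ Znm.T / Z.shape[1]
    elif missing_policy == "pairwise":
        Znm = np.nan_to_num(Z)
        obs = (~np.isnan(Z)).astype(float)
        L_pair = obs @ obs.T
        if np.any(L_pair == 0):
            i, j = np.argwhere(L_pair == 0)[0]
            raise ValueError(
                f"no jointly observed polymorphic marker for pair "
                f"({G.line_ids[i]}, {G.line_ids[j]})"
            )
        K = (Znm @ Znm.T) / L_pair
    else:
        raise ValueError("missing_policy must be 'pairwise' or 'mean'")
    return KinshipMatrix((K + K.T) / 2, "K_FREQ", list(G.line_ids),
                         n_markers_used=int(mask.sum()))


def kinship_ibs(G: GenotypeMatrix) -> KinshipMatrix:
    """Proportion of shared alleles over pairwise-complete markers.

    The per-marker sharing score is ``1 - |d_i - d_j|`` on doses, i.e. 1 for
    equal doses, 0.5 when exactly one line is heterozygous, 0 for opposite
    homozygotes.
    """
    X = G.dose
    obs = (~np.isnan(X)).astype(float)
    L_pair = obs @ obs.T
    if np.any(L_pair == 0):
        i, j = np.argwhere(L_pair == 0)[0]
        raise ValueError(
            f"no jointly observed marker for pair ({G.line_ids[i]}, {G.line_ids[j]})"
        )
    Xz = np.nan_to_num(X)
    # sum over jointly observed markers of |d_i - d_j|:
    #   |d_i - d_j| has no closed bilinear form, use the identity
    #   sum |di-dj| over joint = sum (di+dj) - 2*sum min(di,dj); simpler to
    #   expand via the three indicator channels of the dose alphabet.
    channels = [(Xz == v).astype(float) * obs for v in (0.0, 0.5, 1.0)]
    shared = (
        channels[0] @ channels[0].T
        + channels[1] @ channels[1].T
        + channels[2] @ channels[2].T
        + 0.5 * (channels[1] @ (channels[0] + channels[2]).T)
        + 0.5 * ((channels[0] + channels[2]) @ channels[1].T)
    )
    K = shared / L_pair
    return KinshipMatrix((K + K.T) / 2, "IBS", list(G.line_ids),
                         n_markers_used=G.n_markers)


def kinship_chr(
    G: GenotypeMatrix, chrom: int, missing_policy: str = "pairwise"
) -> KinshipMatrix:
    """K_FREQ on all markers *not* on ``chrom`` (leave-one-chromosome-out)."""
    off = (G.markers["chrom"] != chrom).to_numpy()
    if not (off & _polymorphic_mask(G)).any():
        raise ValueError(f"no polymorphic marker outside chromosome {chrom}")
    K = kinship_freq(G, marker_mask=off, missing_policy=missing_policy)
    return KinshipMatrix(K.matrix, "K_CHR", K.line_ids, excluded_chrom=chrom,
                         n_markers_used=K.n_markers_used)


def pcoa(K: KinshipMatrix, k: int = 3) -> PCoAResult:
    """Classical metric scaling of the genetic distance D = 1 - K.

    D is double-centered (B = -1/2 J D J), eigendecomposed, and the top-k
    axes with positive eigenvalues retained; percent variance uses the sum
    of positive eigenvalues (negatives clipped for the denominator only).
    """
    D = 1.0 - K.matrix
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    k_eff = min(k, int(pos.sum()))
    if k_eff < k:
        warnings.warn(f"only {k_eff} positive axes available (requested {k})")
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    pct = 100.0 * vals[:k_eff] / vals[pos].sum()
    return PCoAResult(coords, vals, pct, list(K.line_ids))
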