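"""Multi-technology concordance, imputation merging, and SNP resampling schemes.

Concordance follows the reference-technology convention: strata
(homozygote / heterozygote) are defined by the reference call, the call
rate is the fraction of reference-called entries also called in the test
panel, and the concordance the fraction of jointly-called entries with
equal dose.  The GBS4/GBS5 rules merge a primary (partially imputed) panel
with a secondary fully-imputed panel.  The MAF and density resampling
schemes draw stratified marker subsets used to study ascertainment and
density effects on QTL detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneticMap, GenotypeMatrix, project_position
from .popgen import KinshipMatrix

MAF_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)  # (0-0.1], (0.1-0.2], ... (0.4-0.5]

#: named MAF-class frequency vectors; the Low_MAF vector mirrors High_MAF
#: (skew toward rare alleles) — see docs/methods.md on this choice.
NAMED_MAF_SCHEMES = {
    "Flat_MAF": (0.2, 0.2, 0.2, 0.2, 0.2),
    "High_MAF": (0.0, 0.0, 0.2, 0.4, 0.4),
    "Low_MAF": (0.4, 0.4, 0.2, 0.0, 0.0),
}


@dataclass
class ConcordanceReport:
    n_common_markers: int
    n_lines: int
    total_concordance_pct: float
    total_call_rate_pct: float
    hom_concordance_pct: float
    hom_call_rate_pct: float
    het_concordance_pct: float
    het_call_rate_pct: float
    counts: dict = field(default_factory=dict)
    n_excluded_markers: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": ["total", "homozygotes", "heterozygotes"],
                "concordance_pct": [
                    self.total_concordance_pct,
                    self.hom_concordance_pct,
                    self.het_concordance_pct,
                ],
                "call_rate_pct": [
                    self.total_call_rate_pct,
                    self.hom_call_rate_pct,
                    self.het_call_rate_pct,
                ],
            }
        )


@dataclass
class SamplingScheme:
    kind: str  # MAF_SCHEME | DENSITY_SCHEME
    name: str
    frequencies: tuple | None = None  # MAF schemes: 5 bin frequencies
    reference: GenotypeMatrix | None = None  # empirical schemes
    window_bp: int = 10_000_000


def _align_common(test: GenotypeMatrix, reference: GenotypeMatrix):
    """Common (chrom, pos) markers with compatible alleles, common lines."""
    t = test.markers.assign(_ti=np.arange(test.n_markers))
    r = reference.markers.assign(_ri=np.arange(reference.n_markers))
    merged = t.merge(r, on=["chrom", "pos_bp"], suffixes=("_t", "_r"))
    compatible = merged["allele_labels_t"].astype(str) == merged["allele_labels_r"].astype(str)
    n_excluded = int((~compatible).sum())
    merged = merged[compatible]
    lines = [l for l in reference.line_ids if l in set(test.line_ids)]
    ti = [test.line_ids.index(l) for l in lines]
    ri = [reference.line_ids.index(l) for l in lines]
    Xt = test.dose[np.ix_(ti, merged["_ti"].to_numpy())]
    Xr = reference.dose[np.ix_(ri, merged["_ri"].to_numpy())]
    return Xt, Xr, len(merged), len(lines), n_excluded


def concordance(test: GenotypeMatrix, reference: GenotypeMatrix) -> ConcordanceReport:
    """Genotype concordance and call rates of ``test`` against ``reference``."""
    Xt, Xr, n_common, n_lines, n_excl = _align_common(test, reference)
    if n_common == 0:
        raise ValueError("no common marker with compatible alleles")
    ref_called = ~np.isnan(Xr)
    joint = ref_called & ~np.isnan(Xt)
    eq = joint & (Xt == Xr)
    strata = {
        "total": ref_called,
        "hom": ref_called & (Xr != 0.5),
        "het": ref_called & (Xr == 0.5),
    }
    pct = {}
    counts = {}
    for name, mask in strata.items():
        n_ref = int(mask.sum())
        n_joint = int((joint & mask).sum())
        n_eq = int((eq & mask).sum())
        counts[name] = {"ref_called": n_ref, "joint_called": n_joint, "equal": n_eq}
        pct[name + "_call"] = 100.0 * n_joint / n_ref if n_ref else np.nan
        pct[name + "_conc"] = 100.0 * n_eq / n_joint if n_joint else np.nan
    return ConcordanceReport(
        n_common_markers=n_common,
        n_lines=n_lines,
        total_concordance_pct=pct["total_conc"],
        total_call_rate_pct=pct["total_call"],
        hom_concordance_pct=pct["hom_conc"],
        hom_call_rate_pct=pct["hom_call"],
        het_concordance_pct=pct["het_conc"],
        het_call_rate_pct=pct["het_call"],
        counts=counts,
        n_excluded_markers=n_excl,
    )


def merge_imputations(
    primary: GenotypeMatrix, secondary: GenotypeMatrix, mode: str = "GBS5"
) -> GenotypeMatrix:
    """Combine a primary panel with a secondary (imputed) panel.

    GBS5: keep homozygous primary calls (0 or 1); heterozygous and missing
    entries take the secondary's value.  GBS4: heterozygous primary entries
    become missing first, then every missing entry is filled from the
    secondary.  Both panels must share line and marker sets.
    """
    if primary.line_ids != secondary.line_ids:
        raise ValueError("panels must share the same line set (same order)")
    if not primary.markers[["chrom", "pos_bp"]].equals(
        secondary.markers[["chrom", "pos_bp"]]
    ):
        raise ValueError("panels must share the same marker set")
    P = primary.dose.copy()
    S = secondary.dose
    if mode == "GBS5":
        replace = (P == 0.5) | np.isnan(P)
    elif mode == "GBS4":
        P[P == 0.5] = np.nan
        replace = np.isnan(P)
    else:
        raise ValueError("mode must be 'GBS4' or 'GBS5'")
    out = np.where(replace, S, P)
    still_missing = int((replace & np.isnan(S)).sum())
    if still_missing:
        warnings.warn(f"{still_missing} entr(ies) remain missing after merge")
    tags = sorted(
        {t for ts in pd.concat([primary.markers["tech_tags"],
                                secondary.markers["tech_tags"]])
         for t in str(ts).split(",") if t}
    )
    markers = primary.markers.copy()
    markers["tech_tags"] = ",".join(tags)
    return GenotypeMatrix(list(primary.line_ids), markers, out)


# ---------------------------------------------------------------------------
# Resampling schemes
# ---------------------------------------------------------------------------

def _largest_remainder(quota: np.ndarray, n: int) -> np.ndarray:
    """Integer quotas summing to n, proportional to ``quota`` (deterministic)."""
    if quota.sum() <= 0:
        return np.zeros_like(quota, dtype=int)
    raw = quota / quota.sum() * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def maf_bin_frequencies(G: GenotypeMatrix, min_maf: float = 0.05) -> np.ndarray:
    """Empirical frequency of the five MAF classes in a panel (MAF >= min_maf)."""
    maf = G.maf()
    maf = maf[np.isfinite(maf) & (maf >= min_maf)]
    counts, _ = np.histogram(maf, bins=MAF_BINS)
    return counts / counts.sum()


def sample_by_maf_scheme(
    G: GenotypeMatrix,
    scheme: SamplingScheme | str | tuple,
    n: int,
    seed: int = 0,
    min_maf: float = 0.05,
) -> np.ndarray:
    """Stratified marker sample matching target MAF-class frequencies.

    ``scheme`` is a named vector (Flat_MAF / High_MAF / Low_MAF), a custom
    5-tuple, or a SamplingScheme carrying a reference panel whose empirical
    bin frequencies are matched (GBS_MAF / 600K_MAF style).  The MAF >= 5%
    filter is applied before binning.  Returns marker indices into G.
    """
    if isinstance(scheme, SamplingScheme):
        freqs = (
            maf_bin_frequencies(scheme.reference, min_maf)
            if scheme.reference is not None
            else np.asarray(scheme.frequencies, float)
        )
    elif isinstance(scheme, str):
        freqs = np.asarray(NAMED_MAF_SCHEMES[scheme], float)
    else:
        freqs = np.asarray(scheme, float)
    maf = G.maf()
    eligible = np.isfinite(maf) & (maf >= min_maf)
    bin_idx = np.digitize(maf, MAF_BINS[1:-1], right=True)  # 0..4
    rng = np.random.default_rng(seed)
    avail = np.array([(eligible & (bin_idx == b)).sum() for b in range(5)])
    empty = (avail == 0) & (freqs > 0)
    if empty.any():
        warnings.warn(f"empty MAF bin(s) {np.flatnonzero(empty)}: renormalizing")
        freqs = np.where(avail > 0, freqs, 0.0)
    quotas = _largest_remainder(freqs, n)
    picks = []
    for b in range(5):
        pool = np.flatnonzero(eligible & (bin_idx == b))
        q = quotas[b]
        if q > len(pool):
            warnings.warn(f"MAF bin {b}: requested {q} > available {len(pool)}")
            q = len(pool)
        if q:
            picks.append(rng.choice(pool, size=q, replace=False))
    return np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)


def sample_by_density_scheme(
    G: GenotypeMatrix,
    gmap: GeneticMap,
    scheme: SamplingScheme | str,
    n: int,
    window_bp: int = 10_000_000,
    seed: int = 0,
    min_maf: float = 0.05,
) -> np.ndarray:
    """Marker sample following a target density over contiguous 10-Mbp windows.

    Per-window quotas are proportional to window physical length
    (Dens_Phys), genetic length (Dens_Gen), or the empirical window marker
    counts of a reference panel (Dens_GBS / Dens_600K / Dens_50K style);
    markers are drawn uniformly within windows, largest-remainder rounding.
    """
    name = scheme.name if isinstance(scheme, SamplingScheme) else scheme
    ref = scheme.reference if isinstance(scheme, SamplingScheme) else None
    maf = G.maf()
    eligible = np.isfinite(maf) & (maf >= min_maf)
    wins = []
    for c in gmap.chroms:
        length = gmap.chrom_length_bp[c]
        for s in range(1, length + 1, window_bp):
            wins.append((c, s, min(s + window_bp - 1, length)))
    weights = np.empty(len(wins))
    for k, (c, s, e) in enumerate(wins):
        if name == "Dens_Phys":
            weights[k] = e - s + 1
        elif name == "Dens_Gen":
            weights[k] = project_position(gmap, c, float(e), "bp_to_cM") - project_position(
                gmap, c, float(s), "bp_to_cM"
            )
        else:
            if ref is None:
                raise ValueError(f"scheme {name!r} needs a reference panel")
            rm = ref.markers
            weights[k] = (
                (rm["chrom"] == c) & (rm["pos_bp"] >= s) & (rm["pos_bp"] <= e)
            ).sum()
    quotas = _largest_remainder(weights, n)
    rng = np.random.default_rng(seed)
    m = G.markers
    picks = []
    for (c, s, e), q in zip(wins, quotas):
        if q == 0:
            continue
        pool = np.flatnonzero(
            eligible
            & (m["chrom"] == c).to_numpy()
            & (m["pos_bp"].to_numpy() >= s)
            & (m["pos_bp"].to_numpy() <= e)
        )
        if q > len(pool):
            warnings.warn(f"window {c}:{s}-{e}: requested {q} > available {len(pool)}")
            q = len(pool)
        if q:
            picks.append(rng.choice(pool, size=q, replace=False))
    return np.sort(np.concatenate(picks)) if picks else np.empty(0, dtype=int)


def resampling_experiment(
    G: GenotypeMatrix,
    phenotypes,
    schemes: list,
    n_grid: list[int],
    n_sets: int,
    windows,
    K_chr: dict[int, KinshipMatrix],
    gmap: GeneticMap | None = None,
    situations: list[tuple[str, str]] | None = None,
    threshold: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan + LD_win grouping over resampled marker subsets.

    For each (scheme, n, set) the scheme's marker subset is drawn, the
    mixed-model scan run for each (trait, environment) situation, and the
    significant-SNP and LD_win QTL counts tabulated.
    """
    from .gwas import scan
    from .qtl import group_ld_win

    if situations is None:
        situations = [
            (t, e) for t in phenotypes.traits for e in phenotypes.environments(t)
        ]
    rows = []
    counter = 0
    for scheme in schemes:
        name = scheme.name if isinstance(scheme, SamplingScheme) else str(scheme)
        kind = (
            scheme.kind
            if isinstance(scheme, SamplingScheme)
            else ("DENSITY_SCHEME" if str(scheme).startswith("Dens") else "MAF_SCHEME")
        )
        for n in n_grid:
            for rep in range(n_sets):
                counter += 1
                sub_seed = (seed * 100003 + counter) % (2**31)
                if kind == "MAF_SCHEME":
                    idx = sample_by_maf_scheme(G, scheme, n, seed=sub_seed)
                else:
                    idx = sample_by_density_scheme(G, gmap, scheme, n, seed=sub_seed)
                Gs = G.take_markers(idx)
                n_assoc = 0
                n_qtls = 0
                per_trait: dict[str, list[pd.DataFrame]] = {}
                for trait, env in situations:
                    assoc = scan(Gs, phenotypes.vector(trait, env), K_chr,
                                 trait=trait, environment=env)
                    n_assoc += int((assoc["neglog10p"] > threshold).sum())
                    per_trait.setdefault(trait, []).append(assoc)
                for trait, pooled in per_trait.items():
                    allassoc = pd.concat(pooled, ignore_index=True)
                    if (allassoc["neglog10p"] > threshold).any():
                        n_qtls += len(
                            group_ld_win(allassoc, windows, threshold=threshold,
                                         trait=trait)
                        )
                rows.append((name, n, rep, len(idx), n_assoc, n_qtls))
    return pd.DataFrame(
        rows, columns=["scheme", "n_markers", "set", "n_sampled",
                       "n_associations", "n_qtls"]
    )
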