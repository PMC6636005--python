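"""Synthetic structured inbred panel with map-driven LD and planted QTLs.

The generator emulates the statistical features the analysis relies on,
at desk scale:

* a panel of inbred lines clustered in admixture groups, built as
  recombination mosaics of group-specific founder haplotypes (allele
  frequencies differentiated between groups, Balding-Nichols style);
* a genetic map with a low-recombination pericentromere (~0.1 cM/Mbp)
  flanked by high-recombination arms (~1.5 cM/Mbp): crossovers are placed
  uniformly on the genetic scale, so LD decays with genetic distance and
  stretches physically through the pericentromere;
* technology ascertainment: array-like marker sets drawn with probability
  increasing in MAF (near-uniform spectrum), sequencing-like sets drawn
  uniformly (keeping the L-shaped spectrum) with extra density in
  high-recombination regions plus missingness, symmetric genotype errors
  and heterozygote under-calling;
* multi-environment phenotypes: planted additive QTLs, a polygenic term
  with covariance proportional to the realized kinship, and environment
  noise scaled to a target per-environment heritability.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (ARRAY_HIGH, ARRAY_LOW, SEQ, GeneticMap, GenotypeMatrix,
                   MARKER_COLUMNS, project_position)
from .popgen import KinshipMatrix, StructureMatrix, kinship_freq


@dataclass
class PlantedQTL:
    trait: str
    chrom: int
    pos_bp: int
    var_fraction: float = 0.08  # share of phenotypic variance explained
    environments: list[str] | None = None  # None = active everywhere
    marker_id: str = ""  # filled with the nearest panel marker
    effect: float = np.nan  # dose effect implied by var_fraction


@dataclass
class TechProfile:
    name: str
    tag: str
    n_markers: int
    maf_profile: str  # "uniform_like" | "l_shaped"
    missing_rate: float = 0.0
    error_rate: float = 0.0
    het_undercall: float = 0.0
    high_rec_enrichment: float = 1.0  # sampling weight multiplier in HIGH regions


def default_tech_profiles(n_pool: int = 12_000) -> dict[str, TechProfile]:
    """Array-like and sequencing-like marker subsets mirroring the study:
    a low-density array, a high-density array with roughly tenfold more
    markers, and a GBS-like direct-read set with 63% missingness and
    heterozygote under-calling.  Subset sizes are fractions of the
    available marker pool (~1:10:8 density ratio)."""
    return {
        "ARRAY_LOW": TechProfile("ARRAY_LOW", ARRAY_LOW, int(0.05 * n_pool),
                                 "uniform_like", missing_rate=0.02,
                                 error_rate=0.001),
        "ARRAY_HIGH": TechProfile("ARRAY_HIGH", ARRAY_HIGH, int(0.5 * n_pool),
                                  "uniform_like", missing_rate=0.005,
                                  error_rate=0.001),
        "SEQ": TechProfile("SEQ", SEQ, int(0.4 * n_pool), "l_shaped",
                           missing_rate=0.63, error_rate=0.01,
                           het_undercall=0.5, high_rec_enrichment=2.0),
    }


@dataclass
class SimConfig:
    n_lines: int = 250
    n_chrom: int = 3
    chrom_length_bp: int = 50_000_000
    pericentromere_fraction: float = 0.4  # central LOW-recombination block
    low_rate_cM_per_Mbp: float = 0.1
    high_rate_cM_per_Mbp: float = 1.5
    n_groups: int = 4
    group_proportions: tuple = (0.16, 0.19, 0.22, 0.43)
    n_founders: int = 6  # shared founder-haplotype pool (controls LD ceiling)
    group_founder_bias: float = 0.3  # weight each group puts on its key founder
    mosaic_generations: float = 200.0  # crossover density per Morgan of history
    n_markers: int = 12_000  # sequence-like marker pool
    maf_beta: float = 0.4  # ancestral freq ~ Beta(maf_beta, maf_beta)
    rare_fraction: float = 0.35  # markers carrying a sub-founder rare variant
    residual_het: float = 0.005
    n_environments: int = 6
    h2: float = 0.6  # per trait x environment heritability
    polygenic_var: float = 1.0
    planted_qtls: list[PlantedQTL] = field(default_factory=list)
    traits: tuple = ("trait1",)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.residual_het, self.rare_fraction, self.pericentromere_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for q in self.planted_qtls:
            if not 1 <= q.pos_bp <= self.chrom_length_bp:
                raise ValueError(f"planted QTL position {q.pos_bp} outside chromosome")


@dataclass
class SimTruth:
    groups: np.ndarray  # group index per line
    planted: pd.DataFrame  # one row per planted QTL with realized effect
    var_components: pd.DataFrame  # per trait x environment genetic/residual var
    config: SimConfig


def default_planted_qtls(config: SimConfig) -> list[PlantedQTL]:
    """Well-separated QTLs: one per chromosome arm of the first chromosomes."""
    L = config.chrom_length_bp
    out = []
    spots = [(1, int(L * 0.15)), (1, int(L * 0.85)), (2, int(L * 0.2)),
             (min(3, config.n_chrom), int(L * 0.8))]
    for t in config.traits:
        for c, p in spots[: max(2, min(4, config.n_chrom + 1))]:
            out.append(PlantedQTL(trait=t, chrom=min(c, config.n_chrom), pos_bp=p))
    return out


# ---------------------------------------------------------------------------

def _build_map(config: SimConfig) -> GeneticMap:
    rows = []
    L = config.chrom_length_bp
    lo_start = int(L * (0.5 - config.pericentromere_fraction / 2))
    lo_end = int(L * (0.5 + config.pericentromere_fraction / 2))
    for c in range(1, config.n_chrom + 1):
        cm = 0.0
        anchors = [(c, 1, 0.0)]
        for start, end, rate in (
            (1, lo_start, config.high_rate_cM_per_Mbp),
            (lo_start, lo_end, config.low_rate_cM_per_Mbp),
            (lo_end, L, config.high_rate_cM_per_Mbp),
        ):
            cm += (end - start) / 1e6 * rate
            anchors.append((c, end, cm))
        rows.extend(anchors)
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"]))


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, GeneticMap, StructureMatrix, SimTruth]:
    """Simulate the sequence-density panel, its map, Q matrix and truth."""
    rng = np.random.default_rng(config.seed)
    gmap = _build_map(config)

    # marker positions, uniform on the physical scale
    per_chrom = np.full(config.n_chrom, config.n_markers // config.n_chrom)
    per_chrom[: config.n_markers % config.n_chrom] += 1
    marker_rows = []
    pos_cm_all = []
    for c in range(1, config.n_chrom + 1):
        want = per_chrom[c - 1]
        pos = np.unique(rng.integers(2, config.chrom_length_bp, size=2 * want + 16))
        while len(pos) < want:  # collisions are rare at desk densities
            pos = np.unique(
                np.concatenate([pos, rng.integers(2, config.chrom_length_bp, size=want)])
            )
        pos = np.sort(rng.choice(pos, size=want, replace=False))
        cm = project_position(gmap, c, pos.astype(float), "bp_to_cM")
        pos_cm_all.append(cm)
        for p, g in zip(pos, cm):
            marker_rows.append((f"snp_{c}_{p}", c, int(p), float(g), "A/B", ""))
    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)

    # shared founder-haplotype pool; a small pool gives high local LD (drift
    # ceiling ~ 1 / effective founder number), group structure comes from
    # group-specific founder-usage weights (each group favors its key founder)
    L = len(markers)
    F = config.n_founders
    p_anc = np.clip(rng.beta(config.maf_beta, config.maf_beta, size=L), 0.02, 0.98)
    founders = (rng.random((F, L)) < p_anc[None, :]).astype(float)

    usage = rng.dirichlet(np.full(F, 0.5), size=config.n_groups)
    for g in range(config.n_groups):
        key = np.zeros(F)
        key[g % F] = 1.0
        usage[g] = (1 - config.group_founder_bias) * usage[g] \
            + config.group_founder_bias * key

    # line group assignment (deterministic counts from the proportions)
    counts = np.floor(np.asarray(config.group_proportions[: config.n_groups])
                      * config.n_lines).astype(int)
    counts[-1] += config.n_lines - counts.sum()
    groups = np.repeat(np.arange(config.n_groups), counts)

    # recombination mosaics on the genetic scale
    chrom_col = markers["chrom"].to_numpy()
    dose = np.empty((config.n_lines, L))
    founder_of = np.empty((config.n_lines, L), dtype=np.int8)
    for c in range(1, config.n_chrom + 1):
        on = np.flatnonzero(chrom_col == c)
        cm = markers["pos_cM"].to_numpy()[on]
        L_cM = gmap.chrom_length_cM[c]
        rate = config.mosaic_generations / 100.0  # crossovers per cM
        for i in range(config.n_lines):
            n_x = rng.poisson(rate * L_cM)
            cuts = np.sort(rng.random(n_x) * L_cM)
            founder_ids = rng.choice(F, size=n_x + 1, p=usage[groups[i]])
            seg = np.searchsorted(cuts, cm)
            founder_of[i, on] = founder_ids[seg]
            dose[i, on] = founders[founder_ids[seg], on]

    # rare-variant channel: young mutations carried by a random sub-lineage of
    # one founder, giving the sequencing-like L-shaped tail of the spectrum
    n_rare = int(config.rare_fraction * L)
    rare_idx = rng.choice(L, size=n_rare, replace=False)
    for m in rare_idx:
        f_m = rng.integers(0, F)
        q_m = rng.uniform(0.1, 0.7)
        carrier = (founder_of[:, m] == f_m) & (rng.random(config.n_lines) < q_m)
        dose[:, m] = carrier.astype(float)

    # residual heterozygosity channel
    het = rng.random(dose.shape) < config.residual_het
    dose[het] = 0.5

    line_ids = [f"L{i + 1:03d}" for i in range(config.n_lines)]
    G = GenotypeMatrix(line_ids, markers, dose)

    # admixture proportions concentrated on the true group
    alpha = np.ones((config.n_lines, config.n_groups))
    alpha[np.arange(config.n_lines), groups] = 30.0
    Q = rng.gamma(alpha)
    Q /= Q.sum(axis=1, keepdims=True)
    Qm = StructureMatrix(Q, line_ids)

    planted = config.planted_qtls or []
    truth = SimTruth(
        groups=groups,
        planted=pd.DataFrame(
            [
                {
                    "trait": q.trait, "chrom": q.chrom, "pos_bp": q.pos_bp,
                    "var_fraction": q.var_fraction, "marker_id": "",
                    "effect": np.nan,
                    "environments": ",".join(q.environments) if q.environments else "",
                }
                for q in planted
            ]
        ),
        var_components=pd.DataFrame(),
        config=config,
    )
    return G, gmap, Qm, truth


def ascertain_technology(
    panel: GenotypeMatrix,
    profile: TechProfile,
    recomb_profile=None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw a technology-specific marker subset and apply its error channels.

    Array-like profiles sample markers with probability proportional to MAF
    (depleting rare alleles, near-uniform spectrum); sequencing-like
    profiles sample uniformly, optionally enriched in high-recombination
    regions, then apply symmetric genotype errors, heterozygote
    under-calling and missingness (in that order).
    """
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    w = np.where(np.isfinite(maf), np.maximum(maf, 1e-4), 0.0)
    if profile.maf_profile == "uniform_like":
        weights = w
    else:
        weights = np.where(w > 0, 1.0, 0.0)
    if profile.high_rec_enrichment != 1.0 and recomb_profile is not None:
        cls = np.concatenate(
            [
                recomb_profile.class_at(c, panel.markers.loc[
                    panel.markers["chrom"] == c, "pos_bp"].to_numpy())
                for c in panel.chroms
            ]
        )
        weights = weights * np.where(cls == "HIGH", profile.high_rec_enrichment, 1.0)
    if profile.n_markers > (weights > 0).sum():
        raise ValueError("requested more markers than available")
    idx = np.sort(
        rng.choice(panel.n_markers, size=profile.n_markers, replace=False,
                   p=weights / weights.sum())
    )
    sub = panel.take_markers(idx)
    dose = sub.dose.copy()

    # symmetric genotype errors (before missingness), then het under-calling
    err = rng.random(dose.shape) < profile.error_rate
    dose[err] = 1.0 - dose[err]  # flips homozygotes, leaves 0.5 in place
    if profile.het_undercall > 0:
        hets = (dose == 0.5) & (rng.random(dose.shape) < profile.het_undercall)
        dose[hets] = rng.integers(0, 2, size=int(hets.sum())).astype(float)
    miss = rng.random(dose.shape) < profile.missing_rate
    dose[miss] = np.nan

    markers = sub.markers.copy()
    markers["tech_tags"] = profile.tag
    return GenotypeMatrix(list(sub.line_ids), markers, dose)


def simulate_phenotypes(
    panel: GenotypeMatrix,
    truth: SimTruth,
    config: SimConfig | None = None,
    K: KinshipMatrix | None = None,
    seed: int | None = None,
    min_qtl_maf: float = 0.2,
):
    """Multi-environment phenotypes from planted QTLs + polygenic background.

    The polygenic term is drawn with covariance proportional to the
    panel's realized K_Freq; environment noise is scaled so that
    genetic variance / total variance hits the configured h2.  Planted
    QTL effects are solved from their target variance fractions:
    with total variance V, sum of QTL fractions v and polygenic variance
    s2_u, V = s2_u / (h2 - v).  Updates ``truth`` in place with the
    realized effects and variance components, and returns a
    PhenotypeTable.
    """
    from .core import PhenotypeTable

    config = config or truth.config
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    n = panel.n_lines
    envs = [f"env{k + 1}" for k in range(config.n_environments)]

    if K is None:
        K = kinship_freq(panel, missing_policy="mean")
    vals, vecs = np.linalg.eigh(K.matrix)
    rootK = (vecs * np.sqrt(np.maximum(vals, 0))) @ vecs.T

    planted = truth.planted
    records = []
    var_rows = []
    pos = panel.markers["pos_bp"].to_numpy()
    chrom = panel.markers["chrom"].to_numpy()
    for t in config.traits:
        u = rootK @ rng.standard_normal(n)

        rows = planted[planted["trait"] == t] if len(planted) else planted
        v_sum = float(rows["var_fraction"].sum()) if len(rows) else 0.0
        if v_sum >= config.h2:
            raise ValueError("sum of QTL variance fractions must be < h2")
        V_total = config.polygenic_var / (config.h2 - v_sum)
        qtl_part = np.zeros(n)
        qtl_doses = []
        maf = panel.maf()
        for ridx, q in rows.iterrows():
            # candidates: common markers near the requested position (planted
            # causal variants are intermediate-frequency polymorphisms; rare
            # sub-lineage markers are heavily confounded with kinship).  Among
            # them, plant on the marker least collinear with relatedness
            # (minimal kinship quadratic form x'Kx): a structure-aligned
            # "causal" marker measures confounding, not power.
            near = np.abs(pos - q["pos_bp"]) < 2_500_000
            on = np.flatnonzero((chrom == q["chrom"]) & (maf >= min_qtl_maf) & near)
            if on.size == 0:
                on = np.flatnonzero((chrom == q["chrom"]) & (maf >= min_qtl_maf))
            if on.size == 0:
                on = np.flatnonzero(chrom == q["chrom"])
            X = panel.dose[:, on]
            X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
            Xc = X - X.mean(axis=0)
            norms = np.linalg.norm(Xc, axis=0)
            norms[norms == 0] = 1.0
            Xn = Xc / norms
            align = np.einsum("ij,ij->j", Xn, K.matrix @ Xn)
            j = on[np.argmin(align)]
            x = panel.dose[:, j]
            x = np.where(np.isnan(x), np.nanmean(x), x)
            sx = np.std(x)
            if sx == 0:
                raise ValueError("planted QTL landed on a monomorphic marker")
            b = np.sqrt(q["var_fraction"] * V_total) / sx
            qtl_part += b * (x - x.mean())
            qtl_doses.append(x - x.mean())
            planted.loc[ridx, "marker_id"] = panel.markers["marker_id"].iloc[j]
            planted.loc[ridx, "effect"] = b
        # background and noise are drawn orthogonal (in-sample) to the planted
        # causal doses, so each planted QTL explains exactly its configured
        # variance fraction instead of drifting with chance marker-background
        # correlation (which is large in structured panels); this separates
        # power measurement from effect-size sampling noise
        qx = None
        if qtl_doses:
            Xq = np.column_stack(qtl_doses)
            qx, _ = np.linalg.qr(Xq)
            u = u - qx @ (qx.T @ u)
        su = np.std(u)
        u = u / (su if su > 0 else 1.0) * np.sqrt(config.polygenic_var)
        g = qtl_part + u
        var_g = float(np.var(g))
        sigma_e2 = (1 - config.h2) / config.h2 * var_g
        for env in envs:
            e = rng.standard_normal(n)
            if qx is not None:
                e = e - qx @ (qx.T @ e)
            se_ = np.std(e)
            e = e / (se_ if se_ > 0 else 1.0) * np.sqrt(sigma_e2)
            y = g + e
            var_rows.append((t, env, var_g, sigma_e2, var_g / (var_g + np.var(e))))
            records.extend(
                (lid, env, t, yy) for lid, yy in zip(panel.line_ids, y)
            )
    truth.var_components = pd.DataFrame(
        var_rows, columns=["trait", "environment", "var_g", "var_e", "realized_h2"]
    )
    return PhenotypeTable(
        pd.DataFrame(records, columns=["line_id", "environment", "trait",
                                       "adjusted_mean"])
    )


def fixture_config(seed: int = 1) -> SimConfig:
    """Small continuous-integration fixture: 2 chromosomes, 5,000 markers,
    120 lines, 2 environments."""
    cfg = SimConfig(
        n_lines=120,
        n_chrom=2,
        chrom_length_bp=30_000_000,
        n_markers=5000,
        n_environments=2,
        seed=seed,
    )
    cfg.planted_qtls = [
        PlantedQTL("trait1", 1, int(0.2 * cfg.chrom_length_bp), 0.25),
        PlantedQTL("trait1", 2, int(0.75 * cfg.chrom_length_bp), 0.25),
    ]
    return cfg
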