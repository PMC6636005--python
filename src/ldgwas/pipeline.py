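"""End-to-end pipeline: simulate -> QC -> kinship -> LD decay -> windows ->
coverage -> scan -> thresholds -> QTL grouping -> reports.

Driven by a single YAML config; every random draw derives from the root
seed, all artifacts are TSV/JSON under one output directory, and a manifest
records parameters, package version and the SHA-256 of every table so a
rerun can be checked for byte identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, core, decay, gwas, ld, popgen, qtl, simulate, tech

log = logging.getLogger("ldgwas")

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {},  # SimConfig field overrides
    "qc": {"max_het": 0.15, "max_missing": 0.20, "min_maf_diversity": 0.01,
           "min_maf_gwas": 0.05, "ind_max_het": 0.06, "ind_max_missing": 0.10},
    "ld": {"n_pairs": 20000, "n_sets": 3, "max_dist_cM": 1.0},
    "windows": {"threshold": 0.1},
    "coverage": {"window_sizes_kbp": [100, 500, 2000]},
    "gwas": {"alpha": 0.05, "block_size": 200, "explained_variance": 0.995,
             "thresholds": [5.0, 8.0]},
    "qtl": {"discovery_threshold": 5.0, "ld_adj_threshold": 0.5},
    "imputation_error_rate": 0.04,
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["files"][path.name] = _sha256(path)


def run_pipeline(config, outdir) -> dict:
    """Run every stage on a simulated panel; returns the manifest dict."""
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="[%(name)s:%(levelname)s] %(message)s")
    manifest = {"version": __version__, "config": cfg, "files": {}}
    seed = int(cfg["seed"])
    rng_seed = np.random.SeedSequence(seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ["simulate", "tech", "ld", "resample"], rng_seed.spawn(4)
        )
    }

    # -- 1. simulate ------------------------------------------------------
    log.info("simulate: building panel")
    sim_kwargs = dict(cfg.get("simulate") or {})
    planted = sim_kwargs.pop("planted_qtls", None)
    sim_cfg = simulate.SimConfig(seed=stage_seeds["simulate"], **sim_kwargs)
    if planted:
        sim_cfg.planted_qtls = [simulate.PlantedQTL(**q) for q in planted]
    elif not sim_cfg.planted_qtls:
        sim_cfg.planted_qtls = simulate.default_planted_qtls(sim_cfg)
    panel, gmap, Q, truth = simulate.simulate_panel(sim_cfg)
    profile = core.recomb_profile(gmap)
    phenos = simulate.simulate_phenotypes(panel, truth)
    _write(gmap.anchors, out / "map.tsv", manifest)
    _write(profile.windows, out / "recomb_profile.tsv", manifest)
    _write(phenos.records, out / "phenotypes.tsv", manifest)
    _write(truth.planted, out / "truth_planted_qtls.tsv", manifest)

    # -- 2. technologies + concordance + GBS5 merge -----------------------
    log.info("tech: ascertainment and imputation merge")
    profiles = simulate.default_tech_profiles(panel.n_markers)
    tech_panels = {}
    for k, (name, prof) in enumerate(profiles.items()):
        tech_panels[name] = simulate.ascertain_technology(
            panel, prof, profile, seed=stage_seeds["tech"] + k
        )
    # an "imputed" complete SEQ panel: same markers, small error, no missing
    seq_direct = tech_panels["SEQ"]
    imputed_profile = simulate.TechProfile(
        "SEQ_IMPUTED", core.SEQ, seq_direct.n_markers, "l_shaped",
        missing_rate=0.0, error_rate=float(cfg["imputation_error_rate"]),
    )
    rng = np.random.default_rng(stage_seeds["tech"] + 100)
    imp_dose = _apply_errors(panel, seq_direct, imputed_profile, rng)
    seq_imputed = core.GenotypeMatrix(
        list(seq_direct.line_ids), seq_direct.markers, imp_dose
    )
    seq5 = tech.merge_imputations(seq_direct, seq_imputed, mode="GBS5")
    conc_rows = []
    for ref_name in ("ARRAY_LOW", "ARRAY_HIGH"):
        for test_name, test_panel in (("SEQ_direct", seq_direct), ("SEQ_GBS5", seq5)):
            try:
                rep = tech.concordance(test_panel, tech_panels[ref_name])
            except ValueError:
                continue
            df = rep.to_frame()
            df.insert(0, "test", test_name)
            df.insert(1, "reference", ref_name)
            df.insert(2, "n_common", rep.n_common_markers)
            conc_rows.append(df)
    if conc_rows:
        _write(pd.concat(conc_rows, ignore_index=True), out / "concordance.tsv", manifest)
    tech_panels["SEQ"] = seq5

    # -- 3. QC + merge ----------------------------------------------------
    log.info("qc: per-technology filters, then merge")
    qc = cfg["qc"]
    filtered = {}
    for name, p in tech_panels.items():
        p = core.filter_individuals(p, qc["ind_max_het"], qc["ind_max_missing"])
        filtered[name] = core.filter_markers(
            p, qc["max_het"], qc["max_missing"], qc["min_maf_gwas"]
        )
    merged = core.merge_panels(list(filtered.values()))
    core.write_dose_table(merged, out / "merged.dose.tsv", out / "merged.markers.tsv")
    manifest["files"]["merged.dose.tsv"] = _sha256(out / "merged.dose.tsv")
    manifest["files"]["merged.markers.tsv"] = _sha256(out / "merged.markers.tsv")

    # -- 4. kinship + PCoA ------------------------------------------------
    log.info("kinship: K_Freq, IBS, K_Chr, PCoA")
    K = popgen.kinship_freq(merged, missing_policy="mean")
    ibs = popgen.kinship_ibs(merged)
    K.to_tsv(out / "kinship_kfreq.tsv")
    ibs.to_tsv(out / "kinship_ibs.tsv")
    manifest["files"]["kinship_kfreq.tsv"] = _sha256(out / "kinship_kfreq.tsv")
    manifest["files"]["kinship_ibs.tsv"] = _sha256(out / "kinship_ibs.tsv")
    pc = popgen.pcoa(K, k=3)
    _write(
        pd.DataFrame(pc.coordinates, columns=[f"axis{i+1}" for i in range(pc.coordinates.shape[1])])
        .assign(line_id=pc.line_ids),
        out / "pcoa.tsv",
        manifest,
    )
    K_chr = {c: popgen.kinship_chr(merged, c, missing_policy="mean")
             for c in merged.chroms}

    # -- 5. LD decay ------------------------------------------------------
    log.info("ld: pair sampling and Hill-Weir fits")
    ldcfg = cfg["ld"]
    fit_rows = []
    fits = {}
    for c in merged.chroms:
        for cls, scale in (("HIGH", "cM"), ("LOW", "bp")):
            sets = ld.sample_locus_pairs(
                merged, profile, cls, n_pairs=int(ldcfg["n_pairs"]),
                n_sets=int(ldcfg["n_sets"]), max_dist_cM=float(ldcfg["max_dist_cM"]),
                seed=stage_seeds["ld"] + 13 * c + (cls == "HIGH"), chrom=c,
            )
            betas, extents = [], []
            for s in sets:
                if len(s) < 100:
                    continue
                pairs = ld.compute_pair_ld(merged, s, K_chr)
                f = decay.fit_hill_weir(pairs, scale, n_sample=merged.n_lines)
                betas.append(f.beta)
                extents.append([f.extents[t] for t in decay.EXTENT_THRESHOLDS])
            if not betas:
                continue
            beta = float(np.median(betas))
            fit = decay.LDDecayFit(c, cls, scale, beta, merged.n_lines, 0.0,
                                   n_pairs=int(ldcfg["n_pairs"]))
            fit.extents = {
                t: decay.ld_extent(fit, t) for t in decay.EXTENT_THRESHOLDS
            }
            fits[(c, cls)] = fit
            ext = np.asarray(extents)
            cv = float(np.std(ext[:, 0]) / np.mean(ext[:, 0])) if len(ext) > 1 else 0.0
            fit_rows.append(
                (c, cls, scale, beta, len(betas), cv,
                 *[fit.extents[t] for t in decay.EXTENT_THRESHOLDS])
            )
    fits_df = pd.DataFrame(
        fit_rows,
        columns=["chrom", "region_class", "scale", "beta", "n_sets", "cv_extent01",
                 "extent_0.1", "extent_0.2", "extent_0.4"],
    )
    _write(fits_df, out / "ld_decay_fits.tsv", manifest)

    # -- 6. windows + coverage --------------------------------------------
    log.info("coverage: LD windows and genome coverage")
    windows = decay.build_ld_windows(
        merged, fits, profile, gmap, threshold=float(cfg["windows"]["threshold"]),
        min_maf=qc["min_maf_gwas"],
    )
    _write(windows.windows, out / "ld_windows.tsv", manifest)
    windows.to_bed(out / "ld_windows.bed")
    manifest["files"]["ld_windows.bed"] = _sha256(out / "ld_windows.bed")
    _write(decay.genome_coverage(windows, gmap), out / "genome_coverage.tsv", manifest)
    _write(
        decay.coverage_profile(windows, gmap,
                               tuple(cfg["coverage"]["window_sizes_kbp"])),
        out / "coverage_profile.tsv", manifest,
    )

    # -- 7. GWAS ----------------------------------------------------------
    log.info("gwas: mixed-model scans")
    assoc_all = []
    for trait in phenos.traits:
        for env in phenos.environments(trait):
            assoc_all.append(
                gwas.scan(merged, phenos.vector(trait, env), K_chr,
                          trait=trait, environment=env,
                          min_maf=qc["min_maf_gwas"])
            )
    assoc = pd.concat(assoc_all, ignore_index=True)
    _write(assoc, out / "associations.tsv", manifest)
    rep = gwas.threshold_report(
        merged, alpha=float(cfg["gwas"]["alpha"]),
        explained_variance=float(cfg["gwas"]["explained_variance"]),
        block_size=int(cfg["gwas"]["block_size"]),
    )
    n_situations = sum(len(phenos.environments(t)) for t in phenos.traits)
    disc = float(cfg["qtl"]["discovery_threshold"])
    n_sig = int((assoc["neglog10p"] > disc).sum())
    fp = gwas.expected_false_positives(
        merged.n_markers, n_situations, 10.0 ** (-disc), observed=max(n_sig, 1)
    )
    manifest["thresholds"] = {
        "M_markers": rep.M_markers, "M_eff": rep.M_eff,
        "bonferroni_neglog10": rep.bonferroni_neglog10,
        "fixed": cfg["gwas"]["thresholds"],
        "n_significant_at_discovery": n_sig,
        "expected_false_positives": fp["expected_rounded"],
    }

    # -- 8. QTL grouping ---------------------------------------------------
    log.info("qtl: LD_win and LD_adj grouping")
    X = ld.whitened_doses(merged, K)
    id_to_col = {m: i for i, m in enumerate(merged.markers["marker_id"])}

    def ld_fn(a: str, b: str) -> float:
        return float((X[:, id_to_col[a]] @ X[:, id_to_col[b]]) ** 2)

    summaries, qtls_by_trait = [], {}
    for trait in phenos.traits:
        sub = assoc[assoc["trait"] == trait]
        if not (sub["neglog10p"] > disc).any():
            qtls_by_trait[trait] = []
            continue
        q_win = qtl.group_ld_win(sub, windows, threshold=disc, trait=trait)
        q_adj = qtl.group_ld_adj(sub, ld_fn, threshold_p=disc,
                                 ld_threshold=float(cfg["qtl"]["ld_adj_threshold"]),
                                 trait=trait)
        qtls_by_trait[trait] = q_win
        for qs in (q_win, q_adj):
            summaries.append(
                qtl.summarize_qtl(qs, sub, merged, phenos, threshold=disc,
                                  profile=profile)
            )
    if summaries:
        summary = pd.concat(summaries, ignore_index=True)
        _write(summary, out / "qtl_summary.tsv", manifest)
        stab = qtl.stability_table(summary[summary["method"] == "LD_WIN"])
        manifest["qtl_stability"] = stab
        if len(qtls_by_trait) > 1:
            _write(qtl.colocalize(qtls_by_trait), out / "qtl_colocalization.tsv",
                   manifest)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    log.info("pipeline complete: %s", out)
    return manifest


def _apply_errors(panel, seq_direct, prof, rng):
    """Doses of the full panel at seq_direct's markers with error channel only."""
    ids = set(seq_direct.markers["marker_id"])
    idx = np.flatnonzero(panel.markers["marker_id"].isin(ids).to_numpy())
    dose = panel.dose[:, idx].copy()
    err = rng.random(dose.shape) < prof.error_rate
    dose[err] = 1.0 - dose[err]
    return dose
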