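"""Shared paths and cached artifacts for the numbered analysis scripts.

Large intermediates (dose tables) live under scratch/analysis/ and are
regenerated on demand; small summary tables go to results/.
"""

from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 1

SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)


def panel_config():
    """The desk-scale study panel: 250 lines, 3 chromosomes, 12,000 markers,
    4 admixture groups, 6 environments, four planted QTLs."""
    from ldgwas.simulate import SimConfig, default_planted_qtls

    cfg = SimConfig(seed=SEED)
    cfg.planted_qtls = default_planted_qtls(cfg)
    return cfg


def load_panel():
    """Simulate (or reuse) the panel and its technology subsets."""
    import pickle

    cache = SCRATCH / "panel.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    from ldgwas.core import recomb_profile
    from ldgwas.simulate import (ascertain_technology, default_tech_profiles,
                                 simulate_panel, simulate_phenotypes)

    cfg = panel_config()
    panel, gmap, Q, truth = simulate_panel(cfg)
    profile = recomb_profile(gmap)
    phenos = simulate_phenotypes(panel, truth)
    profiles = default_tech_profiles(panel.n_markers)
    techs = {
        name: ascertain_technology(panel, prof, profile, seed=SEED + 100 + k)
        for k, (name, prof) in enumerate(profiles.items())
    }
    bundle = dict(panel=panel, gmap=gmap, Q=Q, truth=truth, profile=profile,
                  phenos=phenos, techs=techs)
    with open(cache, "wb") as fh:
        pickle.dump(bundle, fh)
    return bundle


def load_merged():
    """QC-filtered technologies merged into the combined panel (+ K_chr)."""
    import pickle

    cache = SCRATCH / "merged.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    from ldgwas.core import filter_individuals, filter_markers, merge_panels
    from ldgwas.popgen import kinship_chr
    from ldgwas.tech import merge_imputations
    from ldgwas.simulate import TechProfile, ascertain_technology

    b = load_panel()
    # GBS5-style completion of the sequencing panel: homozygous direct-read
    # calls kept, the rest filled from an error-prone imputed panel
    seq = b["techs"]["SEQ"]
    imputed = _imputed_twin(b["panel"], seq)
    seq5 = merge_imputations(seq, imputed, mode="GBS5")
    filtered = {}
    for name, p in {**b["techs"], "SEQ": seq5}.items():
        p = filter_individuals(p)
        filtered[name] = filter_markers(p)
    merged = merge_panels(list(filtered.values()))
    K_chr = {c: kinship_chr(merged, c, missing_policy="mean")
             for c in merged.chroms}
    out = dict(filtered=filtered, merged=merged, K_chr=K_chr, seq5=seq5)
    with open(cache, "wb") as fh:
        pickle.dump(out, fh)
    return out


def _imputed_twin(panel, seq, error_rate=0.04, seed=SEED + 999):
    """A complete 'imputed' copy of the SEQ marker set with 4% errors."""
    import numpy as np
    from ldgwas.core import GenotypeMatrix

    rng = np.random.default_rng(seed)
    ids = set(seq.markers["marker_id"])
    idx = [i for i, m in enumerate(panel.markers["marker_id"]) if m in ids]
    dose = panel.dose[:, idx].copy()
    err = rng.random(dose.shape) < error_rate
    dose[err] = 1.0 - dose[err]
    return GenotypeMatrix(list(panel.line_ids), seq.markers, dose)
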