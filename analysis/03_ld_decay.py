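"""Kinship-corrected LD decay per chromosome and recombination class.

Samples random same-class locus pairs within 1 cM, computes r2K with the
leave-one-chromosome-out kinship, fits the Hill-Weir expectation, and
tabulates the genetic (high-recombination) and physical (low-recombination)
LD extents at r2K = 0.1 / 0.2 / 0.4, with their stability across pair sets.
"""

import numpy as np
import pandas as pd

from ldgwas.decay import EXTENT_THRESHOLDS, LDDecayFit, fit_hill_weir, ld_extent
from ldgwas.ld import compute_pair_ld, sample_locus_pairs

from _common import RESULTS, SEED, load_merged, load_panel

N_PAIRS, N_SETS = 30_000, 5


def main() -> None:
    b = load_panel()
    m = load_merged()
    merged, K_chr, profile = m["merged"], m["K_chr"], b["profile"]
    rows = []
    for c in merged.chroms:
        for cls, scale, unit in (("HIGH", "cM", "cM"), ("LOW", "bp", "kbp")):
            sets = sample_locus_pairs(merged, profile, cls, N_PAIRS, N_SETS,
                                      seed=SEED + 13 * c, chrom=c)
            betas, ext01 = [], []
            for s in sets:
                if len(s) < 100:
                    continue
                pairs = compute_pair_ld(merged, s, K_chr)
                f = fit_hill_weir(pairs, scale, n_sample=merged.n_lines)
                betas.append(f.beta)
                ext01.append(f.extents[0.1])
            fit = LDDecayFit(c, cls, scale, float(np.median(betas)),
                             merged.n_lines, 0.0)
            ext = {t: ld_extent(fit, t) for t in EXTENT_THRESHOLDS}
            scale_div = 1.0 if unit == "cM" else 1000.0
            rows.append({
                "chrom": c, "region_class": cls, "unit": unit,
                "n_sets": len(betas),
                "beta": float(f"{fit.beta:.6g}"),
                "extent_0.1": round(ext[0.1] / scale_div, 4),
                "extent_0.2": round(ext[0.2] / scale_div, 4),
                "extent_0.4": round(ext[0.4] / scale_div, 4),
                "cv_extent_0.1_pct": round(
                    100 * np.std(ext01) / np.mean(ext01), 1),
            })
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "ld_decay_fits.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    hi = out[out.region_class == "HIGH"]["extent_0.1"]
    lo = out[out.region_class == "LOW"]["extent_0.1"]
    print(
        f"\nFindings: genetic LD extent (r2K=0.1) in high-recombination arms "
        f"is {hi.min()}-{hi.max()} cM, while the physical extent in the "
        f"pericentromeres reaches {lo.min()}-{lo.max()} kbp — the two-regime "
        f"pattern that motivates class-specific LD windows.  Extent "
        f"variation across pair sets stays below "
        f"{out['cv_extent_0.1_pct'].max()}% (CV)."
    )


if __name__ == "__main__":
    main()
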