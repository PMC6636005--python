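"""Simulate the study panel and its three genotyping-technology subsets.

Writes per-technology marker counts, MAF spectra, gene diversity and call
rates to results/panel_summary.tsv.  The sequencing-like subset should show
the L-shaped spectrum (excess of rare alleles) and heavy missingness; the
array-like subsets a near-uniform spectrum and near-complete calls.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, load_panel


def main() -> None:
    b = load_panel()
    panel = b["panel"]
    rows = []
    for name, G in {"POOL": panel, **b["techs"]}.items():
        maf = G.maf()
        called = ~np.isnan(G.dose)
        rows.append({
            "panel": name,
            "n_markers": G.n_markers,
            "n_lines": G.n_lines,
            "call_rate_pct": round(100 * called.mean(), 2),
            "het_rate_pct": round(100 * float((G.dose == 0.5).sum())
                                  / max(called.sum(), 1), 3),
            "mean_he": round(float(np.nanmean(2 * maf * (1 - maf))), 3),
            "pct_maf_lt_05": round(100 * float(np.nanmean(maf < 0.05)), 1),
            "pct_maf_gt_30": round(100 * float(np.nanmean(maf > 0.30)), 1),
        })
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "panel_summary.tsv", sep="\t", index=False)
    print(out.to_string(index=False))
    seq, arr = out.set_index("panel"), None
    print(
        f"\nFindings: the sequencing-like subset keeps "
        f"{seq.loc['SEQ', 'pct_maf_lt_05']}% rare markers (MAF<5%) vs "
        f"{seq.loc['ARRAY_HIGH', 'pct_maf_lt_05']}% for the high-density "
        f"array, with a call rate of {seq.loc['SEQ', 'call_rate_pct']}% vs "
        f"{seq.loc['ARRAY_HIGH', 'call_rate_pct']}% — the ascertainment-bias "
        f"and missingness contrast the analysis is built around."
    )


if __name__ == "__main__":
    main()
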