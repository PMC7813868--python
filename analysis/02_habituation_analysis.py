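#!/usr/bin/env python
"""Score light-off jump habituation and contrast knockdowns with controls.

Reads the simulated jump cohort, scores trials-to-criterion per fly, applies
the >50%-jumpers genotype filter, fits the log-TTC linear model of each
knockdown against its genetic-background control with a Bonferroni factor
equal to the number of RNAi lines sharing that control, and writes per-fly,
per-genotype, curve, and comparison tables under results/habituation/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ethofly import habituation as hb, stats as st

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "habituation"

# knockdown -> (control, number of RNAi lines sharing that control)
CONTRASTS = {
    "geneA_RNAi1": ("control_1", 3),
    "geneB_RNAi1": ("control_1", 3),
    "geneC_RNAi1": ("control_1", 3),
    "geneA_RNAi2": ("control_2", 2),
    "geneC_RNAi2": ("control_2", 2),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = hb.read_jump_table(DATA / "jumps.csv")
    per_fly = hb.ttc_table(series)
    per_fly.to_csv(OUT / "ttc_per_fly.csv", index=False)

    groups: dict[str, hb.GenotypeHabituation] = {}
    rows, curves = [], {}
    for geno in per_fly["genotype"].unique():
        g = hb.summarize_genotype([s for s in series if s.genotype == geno])
        groups[geno] = g
        rows.append(dict(
            genotype=geno, n_total=g.n_total, n_jumpers=g.n_jumpers,
            jumper_fraction=round(g.jumper_fraction, 3),
            analyzable=hb.filter_genotype(g),
            gm_ttc=round(float(np.exp(np.mean(np.log(g.ttc)))), 2),
        ))
        curves[geno] = g.mean_jump_response
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "genotype_summary.csv", index=False)
    curve_df = pd.DataFrame(curves)
    curve_df.insert(0, "trial", np.arange(1, len(curve_df) + 1))
    curve_df.to_csv(OUT / "mean_jump_curves.csv", index=False)
    print(summary.to_string(index=False))

    comp = []
    for kd, (ctrl, n_rnai) in CONTRASTS.items():
        if not (hb.filter_genotype(groups[kd]) and hb.filter_genotype(groups[ctrl])):
            print(f"{kd}: excluded by the >50% jumper rule")
            continue
        r = st.ttc_glm(groups[kd].ttc, groups[ctrl].ttc, n_rnai=n_rnai,
                       case_label=kd, control_label=ctrl)
        comp.append(dict(
            contrast=r.contrast, fold_change=round(r.fold_change, 2),
            p=r.p, p_adj=r.p_adj, stars=st.significance_stars(r.p_adj),
            n_case=r.n_case, n_control=r.n_control,
        ))
    comp = pd.DataFrame(comp)
    comp.to_csv(OUT / "comparisons.csv", index=False)
    print()
    print(comp.to_string(index=False))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for geno, curve in curves.items():
            style = "--" if geno.startswith("control") else "-"
            ax.plot(curve_df["trial"], curve, style, label=geno, lw=1.2)
        ax.set(xlabel="trial", ylabel="fraction jumping",
               title="Mean jump response over 100 light-off trials")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(OUT / "mean_jump_curves.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
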