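#!/usr/bin/env python
"""Day/night activity-sleep architecture of the simulated DAM cohort.

Parses each 32-channel monitor file, applies dead-fly QC, computes the six
per-phase metrics averaged over 4 days, expresses each knockdown metric as
percent of its genetic-background control, and tests every metric with
one-way ANOVA plus Dunnett's many-to-one post-hoc per control family.
Writes per-fly metrics, comparisons, and the 30-min profile curve under
results/sleep/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ethofly import damio, sleep as sl, stats as st

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "sleep"

FAMILIES = {
    "control_1": ["geneA_RNAi1", "geneB_RNAi1", "geneC_RNAi1"],
    "control_2": ["geneA_RNAi2", "geneC_RNAi2"],
}
METRICS = ["total_activity", "total_sleep_min", "activity_while_awake",
           "sleep_latency_min", "bout_count", "mean_bout_duration_min"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cmap = pd.read_csv(DATA / "channel_map.csv")
    series = []
    for monitor, sub in cmap.groupby("monitor"):
        series += damio.read_dam(DATA / monitor, sub)
    n_before = len(series)
    series = sl.exclude_dead(series)
    print(f"parsed {n_before} flies, {len(series)} pass dead-fly QC")

    metrics = sl.fly_metrics_table(series)
    metrics.to_csv(OUT / "fly_metrics.csv", index=False)
    sl.profile_curve(series).to_csv(OUT / "profile_30min.csv", index=False)

    rows = []
    for control, cases in FAMILIES.items():
        for phase in ("day", "night"):
            sub = metrics[metrics["phase"] == phase]
            for col in METRICS:
                groups = {
                    g: sub.loc[sub["genotype"] == g, col].to_numpy()
                    for g in [control] + cases
                }
                fam = st.anova_dunnett(groups, control=control)
                ctrl_mean = float(np.mean(groups[control]))
                for c in fam.contrasts:
                    case = c.contrast.split(" vs ")[0]
                    pct = float(np.asarray(st.normalize_to_control(
                        float(np.mean(groups[case])), ctrl_mean))) if ctrl_mean else np.nan
                    rows.append(dict(
                        phase=phase, metric=col, contrast=c.contrast,
                        percent_of_control=round(pct, 1),
                        anova_p=fam.anova_p, p=c.p, p_adj=c.p_adj,
                        stars=st.significance_stars(c.p_adj),
                    ))
    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "comparisons.csv", index=False)
    hits = comp[comp["p_adj"] < 0.05]
    print(f"\n{len(hits)} of {len(comp)} contrasts significant at p_adj < 0.05:")
    print(hits[["phase", "metric", "contrast", "percent_of_control", "p_adj", "stars"]]
          .to_string(index=False))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        prof_all = []
        for geno, idx in pd.Series(range(len(series))).groupby(
            pd.Series([s.genotype for s in series])
        ):
            prof = sl.profile_curve([series[i] for i in idx])
            prof["genotype"] = geno
            prof_all.append(prof)
        prof_all = pd.concat(prof_all)
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        for geno, g in prof_all.groupby("genotype"):
            style = "--" if geno.startswith("control") else "-"
            axes[0].plot(g["zt_hours"], g["activity"], style, label=geno, lw=1)
            axes[1].plot(g["zt_hours"], g["sleep_min"], style, lw=1)
        axes[0].set(ylabel="activity / 30 min")
        axes[1].set(xlabel="ZT (h)", ylabel="sleep min / 30 min")
        for ax in axes:
            ax.axvspan(12, 24, color="0.9", zorder=0)
        axes[0].legend(fontsize=6, ncol=2)
        fig.tight_layout()
        fig.savefig(OUT / "profile_30min.png", dpi=120)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
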