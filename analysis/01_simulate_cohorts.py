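#!/usr/bin/env python
"""Simulate the three study cohorts with known ground truth.

Emulates a pan-neuronal RNAi knockdown screen of three candidate genes
(geneA, geneB, geneC; two RNAi lines for A and C, one for B, two shared
genetic-background controls):

* habituation cohort — ~120 flies/genotype over 100 light-off trials.
  geneA_RNAi2 carries a strong habituation deficit (rate multiplier 0.25,
  calibrated to a ~3-fold geometric-mean TTC increase), geneC both lines
  moderate (0.4), geneA_RNAi1 and geneB none.
* DAM cohort — 32 flies/genotype, 4 days, 30-s bins, 12:12 LD; sleep
  pressure mildly raised for geneA_RNAi1 (1.25) and geneC_RNAi1 (1.1).
* qPCR cohort — brain/body Ct tables across 7 developmental stages for the
  three genes, geneC strongly brain-enriched after metamorphosis.

Writes long-format CSVs, DAM monitor files, and ground-truth sidecars under
results/data/.
"""

from pathlib import Path

import pandas as pd

from ethofly import damio, habituation as hb, simulate as sim

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

HAB_DESIGN = {
    # genotype -> (rate multiplier, control)
    "control_1": (1.0, None),
    "control_2": (1.0, None),
    "geneA_RNAi1": (1.0, "control_1"),
    "geneA_RNAi2": (0.25, "control_2"),
    "geneB_RNAi1": (1.0, "control_1"),
    "geneC_RNAi1": (0.4, "control_1"),
    "geneC_RNAi2": (0.4, "control_2"),
}

SLEEP_PRESSURE = {
    "control_1": 1.0,
    "control_2": 1.0,
    "geneA_RNAi1": 1.25,
    "geneA_RNAi2": 0.85,
    "geneB_RNAi1": 1.15,
    "geneC_RNAi1": 1.1,
    "geneC_RNAi2": 1.0,
}

QPCR_ENRICHMENT = {
    # per-stage brain/body ratio across (L3, PU, PH, A0, A5, A15, A30)
    "geneA": (0.6, 0.6, 1.2, 0.6, 0.6, 0.6, 0.6),
    "geneB": (0.4, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0),
    "geneC": (1.0, 1.0, 4.0, 8.0, 8.0, 8.0, 8.0),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- habituation: 3 replicates x 40 flies per genotype
    all_series, truths = [], []
    for gi, (geno, (effect, _)) in enumerate(HAB_DESIGN.items()):
        for rep in range(3):
            p = sim.HabituationSimParams(
                n_flies=40, genotype=geno, genotype_effect=effect,
                replicate=f"r{rep + 1}", seed=SEED + 100 * gi + rep,
            )
            s, t = sim.simulate_habituation(p)
            all_series += s
            truths.append(t.assign(replicate=f"r{rep + 1}"))
    hb.series_to_frame(all_series).to_csv(OUT / "jumps.csv", index=False)
    pd.concat(truths).to_csv(OUT / "jumps_ground_truth.csv", index=False)
    print(f"habituation: {len(all_series)} flies, {len(HAB_DESIGN)} genotypes")

    # --- DAM: one 32-channel monitor per genotype
    maps = []
    for gi, (geno, pressure) in enumerate(SLEEP_PRESSURE.items()):
        p = sim.DamSimParams(
            n_flies=32, genotype=geno, sleep_pressure=pressure,
            seed=SEED + 1000 + gi,
        )
        series, _ = sim.simulate_dam(p)
        monitor = OUT / f"monitor_{gi + 1:02d}.txt"
        cmap = damio.write_dam(series, monitor)
        cmap.insert(0, "monitor", monitor.name)
        maps.append(cmap)
        sim.write_ground_truth(p, OUT / f"dam_ground_truth_{geno}.json")
    pd.concat(maps).to_csv(OUT / "channel_map.csv", index=False)
    print(f"dam: {len(maps)} monitors x 32 flies, 4 days each")

    # --- qPCR: one Ct table per target gene (shared references)
    tables = []
    for gi, (gene, enr) in enumerate(QPCR_ENRICHMENT.items()):
        p = sim.QpcrSimParams(
            target_gene=gene, brain_enrichment=enr, seed=SEED + 2000 + gi
        )
        tables.append(sim.simulate_qpcr(p))
        sim.write_ground_truth(p, OUT / f"qpcr_ground_truth_{gene}.json")
    # references appear once per target table; keep each table separate
    pd.concat(tables, keys=list(QPCR_ENRICHMENT), names=["panel"]).reset_index(
        level=0
    ).to_csv(OUT / "ct.csv", index=False)
    print(f"qpcr: {len(tables)} target panels x 7 stages x 2 tissues x 3 replicates")


if __name__ == "__main__":
    main()
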