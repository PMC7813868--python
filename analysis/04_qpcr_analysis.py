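#!/usr/bin/env python
"""Developmental expression profiles and brain enrichment from the Ct tables.

For each target gene: per-replicate dCT against the dual reference genes,
replicate-averaged percent-of-max profiles across the seven stages in brain
and body, and the per-stage brain/body enrichment ratio with a paired
t-test.  Writes tables under results/qpcr/.
"""

from pathlib import Path

import pandas as pd

from ethofly import qpcr, stats as st

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "qpcr"
REFERENCES = ["eIF-1A", "alphaTub84B"]
STAGES = ["L3", "PU", "PH", "A0", "A5", "A15", "A30"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ct = pd.read_csv(DATA / "ct.csv")
    profiles, enrichments = [], []
    for panel, sub in ct.groupby("panel"):
        dct = qpcr.delta_ct(sub, panel, REFERENCES)
        profiles.append(qpcr.percent_of_max(dct))
        enr = qpcr.enrichment(dct)
        enr["stars"] = [st.significance_stars(p) for p in enr["p"]]
        enrichments.append(enr)
    prof = pd.concat(profiles, ignore_index=True)
    prof["stage"] = pd.Categorical(prof["stage"], STAGES, ordered=True)
    prof.sort_values(["gene", "tissue", "stage"]).to_csv(
        OUT / "profile_percent_of_max.csv", index=False
    )
    enr = pd.concat(enrichments, ignore_index=True)
    enr["stage"] = pd.Categorical(enr["stage"], STAGES, ordered=True)
    enr = enr.sort_values(["gene", "stage"])
    enr.to_csv(OUT / "enrichment.csv", index=False)

    print("brain/body enrichment (mean ratio, paired-t p):")
    print(enr[["gene", "stage", "mean_ratio", "p", "stars"]]
          .assign(mean_ratio=lambda d: d["mean_ratio"].round(2))
          .to_string(index=False))
    top = enr.loc[enr.groupby("gene")["mean_ratio"].idxmax()]
    print("\nstrongest enrichment per gene:")
    print(top[["gene", "stage", "mean_ratio", "stars"]].to_string(index=False))


if __name__ == "__main__":
    main()
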