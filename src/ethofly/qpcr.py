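"""Relative qPCR quantification by the ddCT method.

Ct tables are tidy DataFrames with columns ``gene, tissue, stage, replicate,
ct``.  For each (tissue, stage, biological replicate) cell the target gene's
Ct is normalized against the arithmetic mean Ct of the reference genes
(dual references, e.g. eIF-1A and alphaTub84B, are standard), giving
dCT = Ct_target - mean(Ct_refs) and a relative quantity 2**(-dCT) assuming
amplification efficiency 2.  Developmental profiles are reported as percent
of the maximum replicate-averaged quantity across stages and tissues of the
same gene; brain-vs-body enrichment is the per-replicate quantity ratio with
a paired t-test on the per-replicate ddCT (brain dCT - body dCT).

Only within-gene comparisons are produced: absolute levels of different
amplicons are not comparable by qPCR, so no cross-gene ratio is ever emitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["delta_ct", "enrichment", "percent_of_max", "read_ct_table"]

_KEYS = ["gene", "tissue", "stage", "replicate"]


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = set(_KEYS + ["ct"])
    if not need.issubset(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(need)}")
    if not np.isfinite(df["ct"]).all():
        raise ValueError("non-finite Ct value in table")
    return df


def delta_ct(
    ct: pd.DataFrame,
    target_gene: str,
    reference_genes: list[str],
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-replicate dCT and relative quantity for one target gene.

    Technical replicates (duplicate rows per gene x tissue x stage x
    biological replicate) are collapsed by mean Ct first.  Raises if any
    target cell lacks reference-gene rows from the same replicate.
    """
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ct = ct.groupby(_KEYS, as_index=False)["ct"].mean()  # collapse technical reps
    tgt = ct[ct["gene"] == target_gene]
    if tgt.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")
    refs = ct[ct["gene"].isin(reference_genes)]
    ref_agg = (
        refs.groupby(["tissue", "stage", "replicate"])["ct"]
        .agg(["mean", "size"])
        .rename(columns={"mean": "ref_ct", "size": "n_ref"})
        .reset_index()
    )
    merged = tgt.merge(ref_agg, on=["tissue", "stage", "replicate"], how="left")
    bad = merged[merged["ref_ct"].isna()]
    if not bad.empty:
        cell = bad.iloc[0]
        raise ValueError(
            "missing reference Ct for cell "
            f"(tissue={cell['tissue']}, stage={cell['stage']}, replicate={cell['replicate']})"
        )
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    merged["rel_quantity"] = efficiency ** (-merged["dct"])
    return merged[_KEYS + ["ct", "ref_ct", "dct", "rel_quantity"]]


def enrichment(
    dct: pd.DataFrame,
    numerator_tissue: str = "brain",
    denominator_tissue: str = "body",
) -> pd.DataFrame:
    """Brain/body enrichment ratio per stage with a paired t-test.

    Replicates are paired across tissues; per replicate the ddCT is
    dCT(brain) - dCT(body) and the ratio 2**(-ddCT).  The two-sided p comes
    from a paired t-test on the dCT pairs.  With zero variance the p is 1
    when the mean difference is 0 (no signal, no noise) and 0 otherwise.
    """
    num = dct[dct["tissue"] == numerator_tissue]
    den = dct[dct["tissue"] == denominator_tissue]
    out = []
    for (gene, stage), g_num in num.groupby(["gene", "stage"], sort=False):
        g_den = den[(den["gene"] == gene) & (den["stage"] == stage)]
        pair = g_num.merge(
            g_den, on=["gene", "stage", "replicate"], suffixes=("_num", "_den")
        )
        if len(pair) != len(g_num) or len(pair) != len(g_den):
            raise ValueError(f"unpaired replicates for {gene} at stage {stage}")
        if len(pair) < 2:
            raise ValueError(f"need >=2 paired replicates for {gene} at stage {stage}")
        ddct = (pair["dct_num"] - pair["dct_den"]).to_numpy()
        ratios = 2.0 ** (-ddct)
        if np.allclose(ddct, ddct[0]):
            t_stat = 0.0 if np.isclose(ddct[0], 0.0) else np.inf * -np.sign(ddct[0])
            p = 1.0 if np.isclose(ddct[0], 0.0) else 0.0
        else:
            t_stat, p = stats.ttest_rel(pair["dct_num"], pair["dct_den"])
        out.append(
            dict(
                gene=gene,
                stage=stage,
                n_replicates=len(pair),
                mean_ratio=float(ratios.mean()),
                mean_ddct=float(ddct.mean()),
                t=float(t_stat),
                p=float(p),
            )
        )
    return pd.DataFrame(out)


def percent_of_max(dct: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged quantities as % of the gene's maximum cell.

    Averages ``rel_quantity`` over replicates per (gene, tissue, stage), then
    scales each gene so its largest stage x tissue cell reads 100.  Scale
    invariant: multiplying a gene's quantities by any c > 0 changes nothing.
    """
    avg = (
        dct.groupby(["gene", "tissue", "stage"], as_index=False, sort=False)[
            "rel_quantity"
        ].mean()
    )
    avg["percent_of_max"] = avg.groupby("gene")["rel_quantity"].transform(
        lambda q: 100.0 * q / q.max()
    )
    return avg
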