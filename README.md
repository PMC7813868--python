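# ethofly

Quantitative phenotyping for Drosophila neurobehavioral genetics: habituation
of the light-off jump reflex, locomotor activity and sleep architecture from
DAM (Drosophila activity monitoring) recordings, and relative gene expression
by qPCR — the three assay arms of a typical pan-neuronal RNAi knockdown
screen of candidate neuropsychiatric-disorder genes. It is written for fly
labs that have rig output (per-trial jump records, TriKinetics monitor files,
Ct tables) and want the scoring rules and statistics applied consistently,
and it ships simulators for every data type so the whole pipeline is testable
without recordings.

## What it computes

**Habituation.** Per fly, the trials-to-criterion
TTC = the 1-based trial of the first jump followed by ≥ 5 consecutive
no-jump trials; flies never meeting the criterion are right-censored at the
last trial. A fly is a *jumper* if it jumps within trials 1–5, and a genotype
is analyzable only if > 50% of its flies are jumpers. Knockdown–control
contrasts are fitted on log TTC with a linear model; with n RNAi lines
sharing one control, p_adj = min(1, p·n).

**Sleep.** Sleep is any ≥ 5-min run of zero-count bins. Six metrics per
phase (day ZT0–12, night ZT12–24), averaged over recording days: total
activity, total sleep, activity while awake, sleep latency, sleep bout
count, mean sleep bout duration. Group contrasts use one-way ANOVA with
Dunnett's many-to-one post-hoc test; the Dunnett adjusted p is evaluated
in-package by quadrature over the equicorrelated multivariate-t max-|t|
distribution:

p_adj = 1 − ∫ f_S(s) ∫ φ(z₀) ∏ᵢ [Φ((|t|s−λᵢz₀)/√(1−λᵢ²)) − Φ((−|t|s−λᵢz₀)/√(1−λᵢ²))] dz₀ ds,  λᵢ = √(nᵢ/(nᵢ+n₀)).

**qPCR.** dCT = Ct(target) − mean Ct(dual references), quantity 2^(−dCT),
developmental profiles as percent of each gene's maximum stage × tissue
cell, and brain/body enrichment 2^(−ddCT) per replicate with a paired
t-test.

See `docs/methods.md` for every convention and numerical choice.

## Worked example

Simulate a two-genotype habituation cohort and score it:

```sh
ethofly simulate --kind habituation --out sim --seed 5 --n-flies 40 \
    --genotype control:1.0 --genotype kd:0.25
ethofly habituation --input sim/jumps.csv --out hab --control control --n-rnai 1
```

`hab/comparisons.csv` then contains (this exact run):

```
contrast,log_ttc_diff,fold_change,p,p_adj,stars,n_case,n_control
kd vs control,0.8801352645202072,2.411225837665762,1.467738381925262e-11,1.467738381925262e-11,***,40,40
```

i.e. the simulated knockdown (habituation rate multiplied by 0.25, a
condition whose population geometric-mean TTC ratio is 3) shows a 2.4-fold
TTC increase in this 40-fly sample at p_adj < 0.001 — the strength of a
severe habituation-deficit hit in a real screen. `hab/genotype_summary.csv`
carries the jumper bookkeeping (here 40/40 jumpers in both genotypes, mean
jumper TTC 37.8 vs 15.75) and `hab/mean_jump_curves.csv` the per-trial
fraction of flies jumping.

The same pattern works for the other arms (`ethofly simulate --kind dam` /
`--kind qpcr`, then `ethofly sleep` / `ethofly qpcr`). The numbered scripts
under `analysis/` run the full screen-scale narrative — simulate seven
genotypes' worth of data (`01`), then habituation (`02`), sleep (`03`) and
expression (`04`) analyses — writing tables under `results/`.

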