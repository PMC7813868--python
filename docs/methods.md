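# Methods

`ethofly` implements the quantitative core of a Drosophila neurobehavioral
phenotyping screen: habituation of the light-off jump reflex, locomotor
activity and sleep architecture from DAM (Drosophila activity monitoring)
beam-break data, and relative gene expression by qPCR. This note records the
models, conventions, and numerical choices, and what the simulation-based
validation does and does not establish.

## Light-off jump habituation

Each fly receives a train of light-off pulses (100 by default) and its jump
response is recorded per trial, either directly as a 0/1 outcome or as a
wing-vibration magnitude thresholded against the rig's noise floor
(`call_jumps`, strict `>` comparison; threshold ≥ 0).

**Trials-to-criterion (TTC).** TTC is the 1-based index of the first jump
trial followed by at least five consecutive no-jump trials. Conventions:

- *First crossing.* Spontaneous recovery after the criterion is ignored; the
  first qualifying trial wins. This makes the score deterministic.
- *End effects.* A jump with fewer than five trials remaining cannot satisfy
  the criterion. Flies with jumps but no qualifying trial are right-censored
  at the last trial (TTC = 100) and retained in analysis — dropping them
  would bias toward faster habituation, because the slowest habituators are
  exactly the censored ones. A sensitivity toggle to exclude censored flies
  is available at the analysis layer (filter on the `censored` column).
- *Jumpers.* A fly is a jumper if it jumps at least once in trials 1–5
  (boundary inclusive). TTC statistics are computed over jumpers only; a fly
  that never jumps has no habituation to measure. Genotypes enter analysis
  only when strictly more than 50% of their flies are jumpers.
- A no-jump run that precedes the first jump never counts toward the
  criterion: the criterion requires a preceding jump.

**Inference.** TTC is analyzed on the natural-log scale (the distribution is
right-skewed and effects are multiplicative; the base only rescales
coefficients, so fold changes are reported as ratios). An ordinary linear
model with a genotype indicator (optional replicate fixed effects; default
genotype-only) gives the contrast; the raw p is the coefficient's t-test and
`p_adj = min(1, p × n_rnai)`, a Bonferroni correction over the RNAi lines
compared against the same genetic-background control in the same experiment.
Without covariates this reduces exactly to a pooled-variance two-sample
t-test on log TTC, which the tests verify.

## DAM sleep architecture

Counts arrive in 30-s bins (any bin width dividing 300 s is accepted) and
are aligned to zeitgeber time from the monitor's clock stamps and a
configured lights-on time; a row's timestamp marks the end of the bin it
summarizes. Day is ZT0–12, night ZT12–24.

**Sleep.** A bin is asleep iff it lies in a maximal run of zero-count bins
spanning ≥ 5 min (≥ 10 bins at 30 s). Bouts are those maximal runs. Missing
bins (file gaps, error-status rows) break candidate runs by default so gaps
never fabricate sleep; bridging is available but off.

**Per-phase metrics** (each computed per day × phase, then averaged over
recording days; incomplete trailing days are excluded with a warning):

| metric | definition | units |
|---|---|---|
| total activity | Σ counts in phase bins | counts |
| total sleep | Σ sleep-bin minutes, bouts split across phases by overlap | min |
| activity while awake | total activity / (720 − total sleep); 0 if fully asleep | counts/min |
| sleep latency | phase start → onset of first bout starting in the phase; 0 if a bout is ongoing at phase start; 720 if none | min |
| sleep bout count | bouts with onset in the phase | — |
| mean bout duration | in-phase minutes of onset-attributed bouts / bout count; 0 if none | min |

Splitting *minutes* by overlap keeps the conservation identity
(day + night sleep = whole-day sleep; awake = 720 − sleep) exact, while
attributing each *bout* to its onset phase keeps bout statistics
unambiguous. Using the in-phase minutes in the duration statistic preserves
`count × mean duration = phase sleep attributable to bouts that started
there`; for the common case of bouts contained in one phase it is simply the
bout duration. Latency is computed from both phase starts; report whichever
phase is of interest. Dead-fly QC (zero counts over the final 24 h) is on by
default at the analysis layer.

Profile curves average summed counts and sleep minutes per 30-min ZT window
over flies and days.

**Inference.** Each metric × phase is tested by one-way ANOVA followed by
Dunnett's many-to-one comparison of the knockdowns against their shared
control, and knockdown means are reported as percent of the control mean.

## Dunnett's test, from first principles

With a control of size n₀ and treatments of sizes nᵢ, the contrast
statistics Tᵢ = (x̄ᵢ − x̄₀)/(s_p √(1/nᵢ + 1/n₀)) follow a k-variate t
distribution with correlations ρᵢⱼ = λᵢλⱼ, λᵢ = √(nᵢ/(nᵢ+n₀)), and ν =
N − (k+1) error degrees of freedom. Writing Tᵢ = (λᵢZ₀ + √(1−λᵢ²)Zᵢ)/S with
independent standard normals and S = √(χ²_ν/ν), the contrasts are
conditionally independent given (Z₀, S), so

P(maxᵢ|Tᵢ| ≤ q) = ∫ f_S(s) ∫ φ(z₀) ∏ᵢ [Φ((qs−λᵢz₀)/√(1−λᵢ²)) −
Φ((−qs−λᵢz₀)/√(1−λᵢ²))] dz₀ ds,

evaluated with 96-node Gauss–Hermite quadrature in z₀ and 128-node
Gauss–Legendre in s over the central 1−10⁻¹² mass of the scaled-chi density.
The two-sided adjusted p is one minus this CDF at |t|; critical values come
from Brent root-finding. At k = 1 the formula collapses exactly to the
two-sample t-test. Agreement is verified two ways: against a 10⁵-draw Monte
Carlo sampler of the same max-|t| law (within 2 decimal places) and against
an independently implemented library routine (scipy's quasi-Monte-Carlo
multivariate-t evaluation, within 2×10⁻³). Small numerical undershoot below
the raw per-contrast p is clipped so `p_adj ≥ p` always holds.

## qPCR relative quantification

dCT = Ct(target) − mean Ct(references) per tissue × stage × biological
replicate, relative quantity 2^(−dCT). Choices: arithmetic-mean aggregation
of the dual reference Cts (equivalent to a geometric mean of reference
quantities — standard dual-reference practice); amplification efficiency
fixed at 2 with a config hook; technical replicates collapsed by mean Ct
before analysis. Developmental profiles are replicate-averaged quantities
scaled so the maximum stage × tissue cell of each gene reads 100% (scale
invariant by construction). Brain/body enrichment is computed per replicate
(ddCT = dCT_brain − dCT_body, ratio 2^(−ddCT)) and tested with a paired
two-sided t-test across replicates; computing enrichment on
replicate-averaged quantities instead is a one-line variant the tables
support. With zero variance the p is 1 at zero mean difference and 0
otherwise. Cross-gene level comparisons are never emitted: qPCR only
compares the same amplicon across conditions.

## Synthetic data generators

The generators draw from the exact models the analyses assume, with the
study's design sizes as defaults; they validate the estimators, not the
biology.

- **Habituation**: fly i jumps at (0-based) trial t with probability
  p₀·exp(−λᵢt); λᵢ is log-normal (median parameterization) around
  λ × genotype effect with log-scale sd σ. Defaults p₀ = 0.9, λ = 0.1,
  σ = 0.3, 100 trials, ~120 flies/genotype — these give jumper fractions
  near 1 and control geometric-mean TTC ≈ 11, comparable to a responsive
  wild-type line. Heterogeneity sits on the rate, not p₀, so initial
  responsiveness (the jumper filter) is controlled separately. The strong-
  knockdown condition uses effect 0.25, calibrated once by forward
  simulation (n = 4000) to a geometric-mean TTC ratio of 3.0; censoring at
  trial 100 compresses the upper tail, which is why the multiplier is
  smaller than 1/3.
- **DAM**: a two-state active/rest Markov chain per fly per 30-s bin with
  phase-dependent transition probabilities (defaults: fall-asleep 0.04/0.08
  and wake 0.06/0.02 per bin for day/night, giving stationary rest fractions
  0.40 and 0.80 and mean rest runs of 8/25 min — siesta-free but otherwise
  fly-like day/night structure over 4 days). A genotype's sleep pressure
  multiplies the fall-asleep and divides the wake probability. Rest bins
  emit 0; active bins emit zero-truncated Poisson counts (rate 2), so the
  rest state is identifiable from the counts — real active flies can of
  course sit still for 30 s, so real data are noisier than this. Monitor
  serialization uses the 32-channel tab-delimited layout with zero padding.
- **qPCR**: Ct = baseline − log₂(expression) + N(0, σ²) with σ = 0.2 Ct,
  3 biological replicates, 7 stages (L3 → adult day 30), two reference genes
  fluctuating around fixed baselines independent of stage and tissue.

What the generators deliberately omit: circadian modulation beyond the
two-phase square wave (no siesta, no anticipation), inter-stimulus-timing
effects and sensitization in habituation, reference-gene instability and
efficiency ≠ 2 in qPCR, and any magnitude-channel realism (the optional
vibration channel is an arbitrary synthetic two-component construct for
threshold testing only). Passing the recovery tests therefore shows the
estimators are correct under the assumed models — not that the models
capture every feature of rig data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 10,000 random series plus
the exhaustive 2¹⁰ length-10 set for the TTC oracle; 10,000 random count
vectors for the sleep-bout oracle; 1,000 null cohorts of 100 vs 100 flies
for the log-TTC type-I error; 2,000 four-group families (n = 20) for the
Dunnett family-wise error; 250 cohorts of 120 vs 120 for power at the
3-fold condition (observed power 1.0, mean fold change ≈ 3.0); 10⁵ Monte
Carlo draws per k for the quadrature cross-check; 50 flies/genotype for the
sleep-pressure ordering. These sizes put Monte-Carlo error well below the
tolerances being checked while keeping a full run in tens of seconds.

## Known limitations

- Censored TTCs enter the log-linear model as the trial cap, which
  understates true effects when censoring is heavy; no survival-style
  likelihood is fitted.
- Sleep latency and bout statistics are onset-attributed; analyses that
  split bouts at ZT boundaries will differ for boundary-spanning bouts.
- The Dunnett evaluation assumes homoscedastic groups (pooled variance), as
  the classical test does.
- The DAM parser infers the bin width from the first timestamp step and
  requires a constant grid; variable-rate files are rejected rather than
  resampled.
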