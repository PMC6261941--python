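# Methods

## The model

`flankerddm` implements a multistage drift-diffusion model (DDM) of the
arrow flanker task.  A single decision variable x(t) accumulates noisy
evidence toward symmetric boundaries at ±a; reaching the positive
boundary triggers a left-hand response, the negative boundary a
right-hand response.  Because the flanking arrows appear 83 ms (one SOA)
before the target, accumulation proceeds in stages, all timed from
flanker onset:

1. **Baseline** (before flanker onset): x sits at the trial's start point
   z_t, drawn uniformly from ±sz/2.  No diffusion noise — the baseline
   reflects response bias only.
2. **Non-decision segment** [0, ter_t): zero-drift diffusion with noise
   scale s.  ter_t is uniform on ter ± st/2.  Because no boundary
   crossing is registered before accumulation begins, this segment is
   simulated as its exact aggregate displacement, a single Gaussian with
   SD s·√ter_t.
3. **Flanker stage** [ter_t, ter_t + SOA): drift = flanker_dir · v_t ·
   f_t.  The flanker weight f_t ~ Normal(f, sf) is untruncated: draws
   above 1 represent trials on which the distractors were not
   suppressed; f < 1 means suppression.
4. **Target stage** (thereafter): drift = target_dir · v_t, with
   v_t ~ Normal(v, sv).

The first sample with |x| ≥ a ends the decision; reported RT is the
crossing time minus the SOA, i.e. referenced to target onset.  Trials
that have not crossed by `max_time` (3 s) are flagged as misses and
excluded from likelihoods.  For display-style trace analyses the
variable subsequently relaxes to baseline at `decay_rate` (default 20/s,
a ~50 ms time constant, mean-reverting as in an Ornstein–Uhlenbeck
process); fitting never simulates baseline or post-response decay.

**Noise scaling.**  Step increments are Normal(drift·dt, s²·dt) with
s = 0.1 and time in seconds, so parameter values are independent of the
1 ms step size.  A literal per-step variance at a fixed step would tie
every other parameter to dt, which we deliberately avoid.

**Distribution conventions.**  Drift and flanker weight vary as
Gaussians (sv, sf); start point and non-decision time vary uniformly
(sz, st), the standard Ratcliff-style convention.  The uniform choice
for sz/st is a design decision; the Gaussian is only specified for
sv/sf.

**Boundary handling.**  Crossings are only checked from ter_t onward.  A
start point near a boundary therefore produces responses clustered just
after accumulation onset rather than instantaneous ones.

## Fitting

RT distributions enter the likelihood as **quantile bin counts**:
empirical quantiles at probabilities .1/.3/.5/.7/.9 (the conventional
set; configurable) are computed per response condition
(congruent-correct, incongruent-correct, incongruent-error — congruent
errors are rare and removed), giving six bins per condition.  The score
of a parameter vector is the joint multinomial log-likelihood of all
bins of all conditions, with condition proportions part of the
prediction so accuracy is fitted along with RT shape.  Because the
staged model has no closed-form first-passage density, predicted bin
probabilities come from simulation (20,000 proposal trials by default)
binned against the observed edges.

A **2% uniform-outlier mixture** floors every bin: the outlier mass is
split equally across response conditions and spread within a condition
proportionally to bin width over the full observed RT range.  This
bounds the influence of contaminant responses and keeps the likelihood
finite when a count falls in an empty predicted bin.

Optimisation uses **differential evolution** (population 15 per free
parameter, crossover 0.9, mutation sampled in [0.5, 1), up to 200
generations, relative tolerance 1e-6 — all configurable through
`DEConfig`).  Common random numbers make the objective a deterministic
function of the parameters: the standard-normal noise matrix and the
standardised parameter draws are generated once per fit and reused for
every proposal, with a trial's realised parameters obtained as affine
transforms of the cached draws.  Because a finite simulation count tilts
the likelihood surface, `DEConfig.n_restarts` runs independent searches
on fresh noise streams and keeps the solution with the best
common-seed re-evaluated likelihood (at `final_n_sim` simulations); this
guards against the v–a–ter ridge trapping a single search.  During
fitting, simulated trials that have not crossed within a ~1.9 s
decision-stage horizon count as misses (real responses that slow fall to
the outlier mixture), which bounds the cached noise matrix.  Paired fits
(post-correct vs post-error) share one simulation seed so that
Monte-Carlo bias largely cancels from parameter differences.

Model variants are nested: DDM1 fixes f = 1 and sf = 0 (no distractor
weighting), DDM2 frees f, DDM3 frees f and sf.  Comparison uses
approximate BIC = −2 logL + k ln n.  Split fits free only (v, a, ter, f)
with the variability parameters fixed to group values to facilitate
convergence; participants with fewer than 30 valid post-error trials are
flagged excluded.

**Default bounds**: v ∈ (0, 10], a ∈ (0, 2], ter ∈ [0.1, 0.6] s,
st, sz ∈ [0, 0.3], sv ∈ [0, 5], f ∈ [−0.5, 2], sf ∈ [0, 1].  Invalid
joint regions inside the box (ter − st/2 < 0, sz/2 ≥ a) are rejected
with a penalty.

## Behavioural statistics

Within-participant single-trial regressions use −1/+1 coding for all
binary factors, `NLD = −ln(1 + trials since the last break)` (breaks
every 200 trials) and `Trial = ln(trial index)`.  The first trial after
each break has undefined history and is excluded from the history
equations.  RT-like responses use robust regression (iteratively
reweighted least squares, bisquare weights with tuning constant 4.685,
MAD scale); binary responses use maximum-likelihood logistic regression
with Wald t-values; perfect separation is flagged and handled with a
light ridge penalty rather than an exception.  Group inference applies
two-sided one-sample t-tests to the per-participant t-values with
Bonferroni correction over the regressor family of one model (the
correction method is a documented default; only "corrected" is
prescribed).

Post-error summaries: PES = median correct-trial RT after errors minus
after correct responses; interference = incongruent − congruent median
correct RT; PERI = interference(post-correct) − interference(post-error);
PIA = incongruent accuracy after errors minus after correct responses.

Participant QC uses an iterative one-sided Grubbs test (α = 0.01) on
per-participant miss and multiple-response rates.

## Beta-power lateralisation (BPL)

Band power (13–25 Hz) comes from complex Morlet wavelets (20 linear
frequency steps over 4–25 Hz, six cycles), log-transformed, band-averaged
and downsampled to 250 Hz; data that already are band power (the
synthetic path) pass through unchanged.  Per participant, each channel
is divided by its pooled SD over trials and samples and then the pooled
mean of the rescaled values is subtracted (divide-then-subtract, as
specified), leaving zero mean and unit SD.  BPL is the contralateral
minus ipsilateral normalised power under the response-hand mapping, so
more negative values mean lateralisation toward the executed response;
relabelling the channel roles negates every derived quantity exactly.

Derived measures:

* **Threshold** — mean BPL within ±12 ms of the button press (7 samples
  at 250 Hz), a proxy for the decision boundary.
* **Slope** — least-squares line slope in a centred 80 ms window (21
  samples) evaluated every 10 samples.  The "step of 10 data points" is
  read as a 10-sample hop (40 ms at 250 Hz); both window and hop are
  configurable.  The estimator is exact for linear signals everywhere
  and for quadratics at the window centre.
* **Onset** — earliest grid time at which per-participant slopes deviate
  from zero by a group t-test with Bonferroni correction over time
  points.  Slope fitting defaults to per-participant averages (the
  single-trial mode exists as well).
* **Peak latency** — time of the most negative response-locked average
  within a ±300 ms search window (the window is a package choice; no
  window is prescribed for the peak).

## Synthetic data

The generator defines the study conditions end to end:

* **Task design** — 1088 trials, 50% congruent, close/far distance,
  short (250 ms) / long (700 ms) response-stimulus interval.  Preceding
  intervals are balanced within every congruence and distance level, and
  the 16 congruence-by-distance transition counts are equalised to ±1 by
  drawing a random Eulerian circuit over the four states (this also
  balances the aggregated congruence and distance transitions).  Breaks
  fall every 200 trials.
* **Behaviour** — trials are simulated sequentially; each trial's
  parameter set is the group set adjusted by its distance (effective
  flanker weight ×1.2 close / ×0.85 far), its preceding interval
  (boundary multiplier, null by default) and the accuracy of the
  previous simulated trial (boundary ×1.3, drift ×0.8, flanker weight
  ×0.6, non-decision time unchanged — the adaptive post-error pattern).
  History is one trial back, matching the analyses' factor set.  The
  realised per-trial parameters and per-trial noise seeds are recorded,
  so any trial replays bit-identically and the within-model regressions
  have ground truth to work on.
* **Group parameters** — v = 2.5, a = 0.16, ter = 0.29 s, f = 0.44,
  sv = 0.5, sz = 0.08, st = 0.12 s, sf = 0.15, s = 0.1.  Non-decision
  time, its width and the flanker weight follow the fitted group values
  (290 ms, 120 ms, 0.44); the remaining values were chosen once so that
  the generator shows the canonical flanker pattern — congruent errors
  rare (<1%), incongruent accuracy ≈ 0.8, interference ≈ 65 ms,
  incongruent errors faster than correct responses — and are not tuned
  thereafter.
* **Beta epochs** — for each responded trial the decision variable is
  signed toward the chosen hand, D(t); the contralateral channel gets
  baseline − ½λ·D(t) and the ipsilateral baseline + ½λ·D(t), plus
  independent white noise per channel and sample, so the expected BPL is
  −λ·D(t).  Defaults (λ = 5, baseline 10, noise SD 1.9) give a
  single-trial signal-to-noise ratio near 0.3, forcing group statistics
  to carry the inference as with real scalp data.  The noise is white
  (no 1/f structure) and the montage is an abstract two-role channel
  pair; the analyses are difference-based and only sign/region
  properties are asserted, so these simplifications do not bear on what
  the tests show.  Passing tests demonstrate internal consistency of the
  pipeline under the assumed signal structure, not properties of real
  EEG.

## Problem sizes in the test suite and acceptance script

Fits in the suite use scaled-down settings chosen as this package's
desk-scale study conditions: 2500–8000 proposal simulations, populations
of 5–8 per parameter, 12–60 generations and up to three restarts, with
narrowed bounds (v ∈ [0.5, 5], a ∈ [0.05, 0.4], ter ∈ [0.15, 0.45] s,
f ∈ [0, 1.2]) that comfortably contain the generator values.  The recovery study fits
(v, a, ter, f) with the variability parameters held at the group values
shared by truth and fit — the same convergence device the split fits
use — because those four parameters are the ones the post-error analyses
interpret.  The model-comparison study likewise fixes (sv, sz, st) in
both variants, preserving the DDM1 ⊂ DDM3 nesting (k = 3 vs k = 5).
Split fits pool ~8700 generated trials (~800 post-error) into one
synthetic participant.  The lateralisation studies use 12–16 synthetic
participants with 600–2400 trials each.

## Numerical choices and degenerate inputs

* dt = 1 ms everywhere; the oracle-equivalence tolerance is 2·dt.
* Quantile edges use the default linear interpolation; bin k is
  [q_k, q_{k+1}) with the outer bins open toward the observed RT range.
  A condition with fewer trials than bins collapses to one bin with a
  warning.
* A zero mixed probability facing a non-zero count returns −inf, never
  an exception; the optimiser sees a large finite penalty.
* Constant regressors are dropped with a warning (rank-deficiency
  contract); zero cross-participant variance in group tests yields an
  infinite t with a flag.
* Ties in the peak search resolve to the earliest sample; a flat signal
  returns an undefined peak.

## Known limitations

* Simulation-based likelihoods carry Monte-Carlo bias at small `n_sim`;
  common random numbers remove proposal-to-proposal jitter but not the
  bias itself, which is why reported likelihoods are re-evaluated at a
  larger count, restarts are compared on a common re-evaluation, and
  paired fits share seeds.
* With few error trials (high boundary, strong suppression) the
  (v, a, ter) trade-off is weakly identified; the split-fit device of
  fixing variability parameters mitigates but does not remove this.
* The synthetic beta signal has no oscillatory content, artefacts or
  volume conduction; `bandpower_timecourse` is exercised on analytic
  signals instead.
* Group inference assumes independent participants and uses Bonferroni
  throughout; no hierarchical modelling is attempted.
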