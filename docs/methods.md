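# Methods

This note records the models, parameter choices, numerical decisions, and
known limitations behind the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task model

The simulated task presents two abstract stimuli; choosing one yields a
monetary gain or loss (±100 JPY). In the **contingent** condition the
advantageous stimulus pays off with probability 0.70 and the other with
0.30; in the **random** condition both pay off with probability 0.50, so
the contingency is unlearnable. A session is 3 blocks × 40 trials per
condition; a response timeout is logged as `choice = none` and counts as
a loss. A **control** condition exists in which the computer makes the
choice (uniformly at random); it shares the logging format.

Outcome scheduling defaults to i.i.d. Bernoulli draws at choice time,
per chosen stimulus (`schedule_mode="bernoulli"`), which is the simplest
reading of "pays off at probability p". An `exact_count` mode draws from
a pre-permuted per-stimulus schedule with exactly round(p·n) gains per
block, for users who want fixed proportions (an all-advantageous chooser
then collects exactly 28 gains in a 40-trial contingent block). The
left/right position of the advantageous stimulus is randomized per trial
and is irrelevant to every statistic, which operates on stimulus
identity. Inter-block rest periods, payment, and reaction times are not
modeled; they affect no computed quantity.

## Agents

Five generative policies span the entropy range: `constant` (sticks with
its first uniformly drawn stimulus), `wsls` (Win-Stay/Lose-Shift,
executed with probability `p_execute`), `outcome_conditioned` (stays with
per-outcome probabilities `p_stay_given_gain`, `p_stay_given_loss` — the
family that parameterizes the entropy statistic directly),
`biased_random` (i.i.d. choice), and `q_softmax` (Rescorla–Wagner update
Q ← Q + α(r − Q) with r ∈ {+1, −1} and softmax choice with inverse
temperature β). On a first trial with no history every agent chooses
uniformly — no information is available. Each agent takes an optional
`lapse_probability` (default 0) producing timeout trials, so the
timeout-handling path of the statistic is exercised. Agents are
generative scaffolding only; the package deliberately does not fit agent
parameters to data, and trial-by-trial inverse-temperature estimation is
out of scope.

`expected_entropy` returns the closed-form asymptotic statistic for the
stationary families — the mean binary entropy of the two conditional stay
probabilities (for `biased_random`, both stay probabilities equal
p² + (1−p)²). For `q_softmax` no stationary closed form exists and the
function signals the caller to simulate.

## The entropy statistic

Transitions are tabulated within blocks only (no carryover across the
long inter-block gaps), starting at each block's second trial. Timeout
trials break the Stay/Shift chain in both directions, since Stay/Shift is
undefined relative to a non-choice. Counts are smoothed with c = 1 and
the four P·log₂P terms are summed and divided by N = 2. Zero counts are
handled entirely by the smoothing — no epsilons inside logarithms.
Response bias is the advantageous-choice rate among responded trials;
reward acquisition is the gain rate over all trials (timeouts count as
losses, matching the payoff rule).

A condition-level value is the unweighted mean of block values. For
entropy a `pooled` aggregation (summing transition counts across blocks
before smoothing) is provided as an alternative, since a single
per-condition entropy can be defined either way; mean-of-blocks is the
default throughout.

Smoothing makes the block estimate biased toward 0.5 at 39 transitions
(and the concavity of the entropy function biases it slightly downward at
high stay asymmetry); at study scale the net effect is an upward shift of
roughly 0.03–0.07 for targets below ~0.75. The estimate converges to the
asymptotic value as trial counts grow (within 0.02 at 10⁵ trials across
the tested parameter grid).

## HRV features

The tachogram places each interbeat interval (ms) at the time of the beat
closing it, interpolates linearly (cubic optional) onto a 4 Hz grid,
removes a least-squares linear trend, and takes a rectangular-window
periodogram of the full record with density scaling, so that the
integrated spectrum equals the variance of the detrended series
(Parseval, verified to 1%). Band powers integrate the PSD by the
trapezoidal rule over half-open bands LF [0.04, 0.15) and HF
[0.15, 0.40) Hz — the 0.15 Hz boundary belongs to HF, avoiding double
counting.

**Total power** for the percentage denominators is the integral over
[0.04, 0.40), i.e. LF% + HF% ≈ 100, and **LF/HF is the ratio of absolute
band powers**, not of log-percentages. Reported panels of this kind in
the literature are not always internally consistent under any single
denominator convention (HF ≈ 51% of LF+HF implies LF/HF ≈ 0.96, whereas
ratios near 0.4 imply a substantial very-low-frequency share in the
denominator); we fix the LF+HF convention because it is self-consistent
and state it explicitly rather than matching any particular printed
panel. Natural logs of the percentages (`ln_lf_pct`, `ln_hf_pct`) are
provided for statistical use.

Change scores subtract each block's baseline panel value from its task
value and average the per-block differences (verified against hand
arithmetic on a printed-style norepinephrine panel: deltas of +8.25,
−11.87, +12.75 average to +3.04 pg/ml). Baseline windows are 2 min and
task windows 4 min, as in the modeled design; no spectral-resolution
compensation is applied between them. Ectopic-beat editing, time-domain
HRV indices, and reconstruction of TPR from pressure waveforms are out of
scope — TPR is consumed as given.

`synthesize_beats` lays down beats by integrating an instantaneous IBI
composed of a mean, an LF tone (0.095 Hz), an HF tone (0.275 Hz), and
white noise. Because a tachogram is effectively sampled at the beat rate
and linearly interpolated — a triangular kernel whose power transfer is
≈ sinc⁴(f·T̄) at mean beat interval T̄ — each tone is pre-emphasized by
the inverse kernel gain so that the *analyzed* series carries the nominal
band power. With this correction the full pipeline recovers an injected
LF/HF ratio within 10% on every tested seed.

## Linkage statistics

* **Correlations**: Pearson r over subjects with two-sided p from the t
  transform on n − 2 df. Exploratory convention: uncorrected, two-sided,
  no multiple-testing correction anywhere.
* **Standardized regression from correlations**: β = R_xx⁻¹ r_yx,
  R² = r_yxᵀβ, adjusted R² = 1 − (1−R²)(n−1)/(n−k−1), overall F on
  (k, n−k−1) df. Verified to 10⁻¹⁰ against least squares on z-scored
  data. Solving from the contingent-condition correlation structure
  (0.63, −0.31, 0.07; n = 16) gives β_NE = 0.655, R² = 0.523, adjusted
  R² = 0.449, F(2,13) = 7.12 — values printed from unrounded raw data
  will differ in the second decimal.
* **Stepwise selection**: forward entry on the smallest coefficient
  p-value below `p_enter = 0.05`, with backward removal above
  `p_remove = 0.10` — conventional defaults, since "stepwise" alone does
  not pin down a variant. An empty model is a valid outcome. The
  selection trace records every entry/removal. Hand-rolled because no
  installed package exposes p-threshold stepwise selection.
* **Repeated-measures ANOVA**: balanced fully within-subject designs of
  any order (2-way condition × block for behavior; 3-way condition ×
  period × block for autonomic panels). Effects are estimated by
  inclusion–exclusion over marginal means and tested against their
  subject interaction. Greenhouse–Geisser ε comes from the covariance of
  orthonormal (Helmert) contrast scores, ε = tr(S)²/(d·ΣS²), clipped to
  [1/d, 1]; ε = 1 exactly for single-df effects. Partial
  η² = SS_effect/(SS_effect + SS_error). F values are verified to 10⁻⁸
  against statsmodels' AnovaRM and ε to 10⁻¹⁰ against pingouin; both
  remain test-side oracles only. Tukey post-hoc tests are out of scope.
* **ROI screens**: per-ROI Pearson correlation with a covariate, flagged
  at two-sided p < .001 with sign — the region-level analogue of a
  voxelwise covariate map at an uncorrected threshold (voxelwise
  inference, spatial preprocessing, and cluster-extent rules have no ROI
  analogue and are not implemented). Seed connectivity correlates one
  ROI's values with every other ROI across subjects.

## Synthetic cohort

Defaults are the study-scale conditions: n = 16 subjects, both reward
conditions, 3 × 40 trials, entropy means 0.64 (contingent) / 0.74
(random) with between-subject SD 0.24 (chosen to reproduce a standard
error of 0.06 at n = 16; subject-level spread is not otherwise
documented), entropy–ΔNE correlation 0.63 in the contingent condition
and 0 in the random condition, ΔNE centered at +3 pg/ml (contingent)
versus −10 pg/ml (random, reproducing the task-period norepinephrine
drop) with SD 15 pg/ml — a spread at which r = 0.63 is detectable at
n = 16 roughly as often as not at conventional thresholds.

Generation: latent z_i ~ N(0,1) → target entropy θ_i (truncated to
(0.05, 0.995)) → symmetric stay parameters (p, 1−p) by inverting the
binary entropy with a bracketed root-finder (round-trip error < 10⁻⁹) →
simulated blocks via the vectorized task engine (pinned exactly to the
scalar TrialRecord path by test). One latent factor couples behavior and
physiology; it is the minimal structure that produces the correlation
pattern being emulated.

ΔNE (and the ΔLF/HF and ROI loadings) couple to the **realized
standardized measured entropy**, not to the latent z. This is deliberate:
with 120 trials per condition the entropy estimate carries sampling noise
(SD ≈ 0.08 against a between-subject SD ≈ 0.22), and coupling to the
latent would attenuate every observable correlation by ~8–10%. The
correlations this generator must calibrate are between *measured*
quantities, so the observable is the right coupling target; the latent z,
θ, and realized policy are stored in the truth table for recovery tests.
Across 2000 cohorts the mean sample entropy–ΔNE correlation sits within
0.03 of the configured 0.63, and with the coupling switched off the
p < .05 flag rate is nominal.

ΔLF/HF is drawn with corr(ΔLFHF, H) = −0.31 and corr(ΔLFHF, ΔNE) = 0.07
in the contingent condition (solved in the same observed-score basis).
ROI values are loading·(standardized ΔNE) + loading·(standardized H) +
unit noise; default loading magnitude 1.8 puts the ROI–covariate
correlation near 0.87, giving ≥ 80% detection at n = 16 under the
p < .001 screen, while unloaded ROIs flag at ≈ the alpha rate. Default
sign structure: negative ΔNE loadings on right posterior insula, rostral
ACC, and parahippocampal gyrus and a negative entropy loading on right
anterior insula (contingent); positive entropy loadings on bilateral
DLPFC and right inferior parietal lobule (random).

Beat series are synthesized per subject × block × period (2 min baseline,
4 min task) with HF percentages drawn around per-condition targets (52%
contingent, 58% random — higher vagal tone under high uncertainty) and a
total LF+HF modulation power of 2000 ms². Panel values for MBP, HR, TPR,
epinephrine, and the HRV indices are drawn around plausible study-scale
levels with per-block noise centered within subject, so a subject's mean
change score equals the coupled target exactly.

Known limitations of the generator: the directly drawn panel LF/HF–HF%
values are not derived from the synthesized beat series (the pipeline
recomputes HRV variables from beats when present, in which case their
change scores carry no configured correlation with entropy); catecholamine
kinetics, baroreflex coupling, and any biophysical brain model are not
attempted — ROI values are a linear-Gaussian stand-in for covariate
structure only. Passing tests therefore demonstrate correctness of the
*pipeline* under the stated generative assumptions, not realism of the
physiology.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; cohort generation
derives independent named streams from `master_seed` via seed-sequence
spawning, so any component is reproducible in isolation. Report tables
round floats only at serialization (6 significant digits) and carry a
manifest hash; identical config + seed reruns are byte-identical.

Simulation sizes used by the validation suite were chosen to make each
property's sampling error small relative to its tolerance while keeping
the suite quick on a single CPU: 10⁴–10⁵ trials for rate and convergence
checks, 100 seeds for spectral recovery, 100 random problems for the
regression oracle, 2000 cohorts for correlation calibration, and 200
cohorts for ROI sign-pattern recovery.
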