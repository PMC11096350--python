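# Methods

## Scope and data model

The pipeline maps single-lead ECG (or pre-extracted RR intervals) from a
two-position stand-up protocol — 5 min supine (S1, decubitus) followed by
5 min standing (S2, orthostatism) — to a per-subject vector of 29 HRV
metrics per position plus their stand-up deltas (S2 − S1), and from the
resulting cohort table to univariate/factorial statistics, a feature
ranking, and a combinatorial classifier benchmark for the diffuse vs
limited cutaneous systemic sclerosis (dcSSc/lcSSc) labels.

Units are fixed package-wide: RR intervals in ms, beat times in s,
sampling rates in Hz, heart rate in bpm. RR series carry per-beat quality
flags (`normal`/`ectopic`/`interpolated`) and maintain the invariant
`beat_times[k] − beat_times[k−1] = intervals[k]/1000`.

The metric registry holds 7 time-domain, 10 frequency-domain and 12
nonlinear metrics. The recurrence-plot quantities Lmin and DIV are
computed and reported by the RQA operation but excluded from the feature
registry: with minimum counted line length 2, Lmin is the constant 2 on
every physiological segment (zero-variance feature), and DIV is exactly
1/Lmax.

## QRS detection

Pan–Tompkins with conventional constants (the algorithm's stages are
standard; no constants are prescribed by the protocol): zero-phase 5–15 Hz
band-pass (2nd-order Butterworth sections, forward–backward), derivative,
squaring, 150 ms moving-window integration, adaptive dual thresholds with
update fraction 0.125 and a 200 ms refractory period. Because the whole
record is available offline, the signal/noise threshold levels are
initialised from global envelope statistics (90th percentile of candidate
peaks / global mean) rather than from the first seconds, which makes the
detector robust to quiet lead-ins. Each trigger is refined to the raw
signal's argmax within ±50 ms so filter delay does not bias RR intervals.
Detection is amplitude-scale invariant and shift-equivariant; flat traces
raise a no-beats error and fs < 100 Hz is rejected.

## Preprocessing

* **Ectopic/artifact rule.** A beat is flagged when its interval deviates
  by more than 30% from the 11-beat running median; flagged intervals are
  replaced by a cubic spline over the remaining (time, interval) points and
  beat times are rebuilt by cumulative sum. The deterministic rule replaces
  interactive visual editing; threshold and window are configurable.
  Segments with more than 20% flagged beats are rejected as a quality gate,
  and subjects failing the gate are excluded from the cohort with a logged
  reason. The correction is idempotent on its own output.
* **Detrending.** 3rd-order least-squares polynomial removal on a
  conditioning-normalised abscissa. It is applied to the 4 Hz resampled
  series ahead of spectral analysis only; time-domain and nonlinear metrics
  consume the corrected beat-to-beat series without detrending (matching
  the convention of the major HRV packages; a flag exposes the detrended
  alternative).
* **Resampling.** Cubic spline through (beat time, interval) evaluated on
  a uniform 4 Hz grid spanning the segment — the equidistant series x(i)
  used by the Welch periodogram.
* **Segments.** Half-open windows [start, start+300 s); the orthostatism
  segment is conventionally placed after a 10 s stand-up noise guard
  (`STANDUP_GUARD_S`, configurable offset).

## Linear-domain metrics

Sample SD (n−1) throughout; mean_HR and sd_HR are the mean and SD of the
per-beat instantaneous rate 60000/RRᵢ; NN50 counts successive differences
strictly greater than 50 ms. The spectrum is Welch's periodogram (Hann
window, segment length min(duration, 256 s), 50% overlap, per-segment mean
removal) on the detrended 4 Hz series. The density is rescaled so its
integral equals the variance of the input exactly; band powers therefore
express genuine ms² of signal variance (Parseval holds by construction)
while peaks, percentages and ratios are unaffected. Bands: VLF
0.003–0.04 Hz (needed by total power and normalized units and therefore
fixed here, configurable), LF 0.04–0.15 Hz, HF 0.15–0.4 Hz. Normalized
units are 100·band/(total − VLF); band peaks are the argmax of the density
inside the band (a centroid variant is available behind a flag). A zero HF
power yields an infinite LF/HF ratio with a warning.

## Nonlinear-domain metrics

* **Poincaré.** SD1² = ½·mean(ΔRR²) and SD2² = 2·var(RR) − ½·mean(ΔRR²)
  (population variance, clipped at zero), so SD1 = RMSSD/√2 holds exactly
  and a strict alternation collapses SD2 to 0.
* **RQA.** Time-delay embedding m=10, τ=1; Euclidean distances; radius
  r = √m·SD of the series (read as √m × SD, the convention of the HRV
  tooling this mirrors; configurable). The line of identity is excluded
  from both the recurrence-rate denominator and the line statistics; no
  additional Theiler window by default. DET counts points on diagonals of
  length ≥ 2; ShanEn is the natural-log entropy of the counted line-length
  histogram (magnitudes ≈ 3–3.5 nats on 5-min segments).
* **DFA.** Integrate the mean-centred series, non-overlapping boxes of
  every integer size in 4–16 (α1) and 16–64 (α2), per-box order-1
  detrending, F(n) = global RMS residual, α = LS slope of log F vs log n.
  The estimator is the field standard and carries the standard small-box
  bias: for uncorrelated noise the exact expectation is
  E[F²(n)] = σ²(n²−4)/(15n), whose slope over boxes 4–16 is ≈ 0.59 rather
  than the asymptotic 0.5 (measured 0.586 at n = 10⁴), while the Brownian
  limit 1.5 is unbiased. No finite-size correction is applied: the known
  white-noise correction √(1−4/n²) would instead bias the Brownian limit
  to ≈ 1.42, and published HRV α1 values come from the uncorrected
  estimator.
* **Entropies.** Chebyshev distance, m=2, r=0.2·SD. ApEn includes
  self-matches (Φ_m − Φ_{m+1}); SampEn excludes them and uses the same
  N−m templates at both lengths, so exact periodicity gives SampEn = 0.
  Zero template matches yield a NaN sentinel with a warning.
* **Correlation dimension.** The correlation sum is the fraction of
  embedded pairs within r, C = (2/M(M−1))·Σ_{i<j} H(r−‖Xᵢ−Xⱼ‖) with
  H(0) = 1. (A printed prefactor of 1/(N(N−1)) over an i<j sum equals half
  this value — a constant that cancels in any log–log slope; the
  fraction-of-pairs convention keeps C → 1 at large r.) For the dimension
  estimate, distances are normalised per coordinate (Euclidean/√m) so that
  radii are commensurate with the series SD at any embedding dimension;
  C is evaluated on a 30-point geometric radius grid over [0.025, 1.0]·SD
  and the dimension is the LS slope of log C vs log r over 5 consecutive
  *usable* grid points (0 < C < 1) positioned nearest r = 0.15·SD on the
  log axis. When the sum is empty near that radius — typical for
  noise-like series at m=10 and 5-min length — the window slides to the
  smallest radii where pairs exist, which is where the r → 0 limit is
  estimable. The slope is clipped to [0, m]; a constant series returns 0.
  This realisation of the limit is a design choice of this package and is
  not bit-compatible with any particular commercial tool.

## Statistics

Univariate group comparisons are gated by Shapiro–Wilk at α = 0.05 in both
groups: Welch's t-test when both pass, Mann–Whitney U otherwise; the chosen
test is reported. Categorical tables use Fisher's exact test for 2×2
tables with any expected cell ≤ 5, chi-square otherwise. The factorial
analysis is a mixed (split-plot) ANOVA — clinical form between subjects,
position within subjects — with Bonferroni ×3 across the three effects per
variable (capped at 1); when the cell residuals fail Shapiro–Wilk the
Scheirer–Ray–Hare rank factorial is used instead, reporting H statistics
against χ² references (ties handled through the rank variance). Subjects
missing a position are excluded listwise with a warning. Correlation
matrices use Pearson when both variables pass normality and Spearman
otherwise, masking entries with p ≥ 0.05. Stand-up deltas are compared
between groups with the same normality-gated two-sample machinery applied
to per-subject deltas.

## Feature engineering

Screening keeps features with unadjusted univariate p < 0.1. Collinearity
pruning walks pairs with R² > 0.9 in descending R² and removes the member
with the lower keep-priority — deltas are preferred over static values,
then a fixed, documented priority list of physiologically primary metrics;
the walk is deterministic and row-order independent. Surviving features
are min–max scaled to [0, 1] (constant features dropped with a warning).
Five selectors rank every feature: random-forest impurity, extra-trees
impurity, univariate F-score, univariate mutual information, and recursive
feature elimination with logistic regression. The aggregate is the
redundancy-weighted score mean_rank + rank_sd (the SD weight is
configurable): a feature is penalised both for ranking poorly on average
and for ranking inconsistently across selectors — our reading of a score
described only as redundancy-weighted, flagged as an interpretation. The
gamma separability index |μ₁−μ₂|/√(σ₁²+σ₂²) gives an independent
discriminability ordering (the original gamma-metric reference is not
reproduced verbatim; the op is pluggable). The final top-k takes the
intersection of both top-k lists first and fills remaining slots by an
arbiter policy — redundancy-score order by default, with an explicit
preference list available to reproduce an expert override.

## Classifier benchmark

Positive class: dcSSc (the clinical target and minority). SMOTE is
implemented from its definition: each synthetic minority row is
x + u·(x_nn − x), u ~ U(0,1), x_nn one of the k = 5 nearest minority
neighbours (k auto-reduced with a warning for tiny minorities); synthesis
runs until parity. By default SMOTE is applied *inside* training folds
only, so synthetic points can never leak into a validation fold (a guard
asserted in the tests); `before_split` reproduces the simpler order of
balancing the whole table first, documented as leakage-prone. All subsets
of 1–5 selected variables (31 for five features; Σ C(24,i) = 55454 shows
why the candidate pool is capped) are crossed with 11 classifier families
(logistic regression, decision tree, random forest, linear and RBF SVM,
single-hidden-layer MLP with 16 units, gradient boosting, a stacked
ensemble of LR+RF+GBM with a logistic meta-learner on out-of-fold
predictions, extra trees, 5-NN, XGBoost), all at library defaults with
fixed seeds. Metrics: MSE is the Brier score of the predicted
positive-class probability; LogLoss on clipped probabilities;
sensitivity/specificity/precision/accuracy at threshold 0.5; trapezoidal
ROC AUC; F1 as the harmonic mean of precision and sensitivity. Held-out
metrics come from the untouched 20% stratified validation split; CV
mean ± SD per metric from 5-fold × 10-repeat stratified CV on the
training set (both are reported because a single protocol can mean
either). The report keeps the best algorithm per combination by held-out
F1, grouped by combination size; the full grid is also emitted and failed
cells are logged without aborting.

## Synthetic cohort generator

The forward model is integral pulse frequency modulation: beats are
emitted where ∫ m(t)/T̄ dt crosses successive integers, with
m(t) = 1 + a_LF·sin(2πf_LF t+φ₁) + a_HF·sin(2πf_HF t+φ₂) + σ·z_β(t),
T̄ = 60/HR. The a_LF/a_HF knobs map directly onto LF/HF band power, and
the 1/f^β noise exponent moves the fractal metrics: a steeper spectrum
(higher β) yields smoother, lower-dimensional dynamics (lower CorDim,
higher DFA α), which is the single knob that produces sign-correct SD2 and
CorDim stand-up deltas without per-metric tuning.

The default two-group preset encodes the study conditions: heart rates
74→88 bpm (diffuse) vs 68→77 bpm (limited); on standing the diffuse cells
lose modulation amplitude and broadband noise while β steepens 0.9→1.8
(variability and complexity fall), and the limited cells gain amplitude
and noise while β flattens 1.2→0.6 (variability and complexity rise).
Subject heterogeneity: a shared log-normal subject factor on HR (σ=0.09)
and on the variability knobs (σ=0.18) applied to both positions (so
within-subject deltas stay coherent), mild per-position jitter (σ=0.02 and
0.05), and subject-specific oscillator frequencies f_LF ~ U(0.08, 0.12) Hz
and f_HF ~ U(0.20, 0.32) Hz, reflecting individual baroreflex resonance
and respiratory rates (and preventing degenerate constant band-peak
features). Group sizes default to 16/42.

What the generator does *not* emulate: respiratory volume coupling, true
baroreflex closed-loop dynamics, non-stationarity within segments,
arrhythmia beyond the simple premature-beat/compensatory-pause injector,
and measurement artifacts other than additive ECG noise. Passing the
pipeline tests on these cohorts therefore demonstrates correct recovery of
planted spectral/fractal structure and classifier plumbing, not clinical
performance; the synthetic groups are more separable than real patients
(benchmark AUCs near 1 at these presets, versus the more modest separation
expected clinically).

## Numerical and testing choices

Test problem sizes are chosen for exhaustiveness per CPU-minute: oracle
equivalence uses 50 series of 25–40 beats against literal double-loop
references at 1e−12; cohort-level direction-recovery checks use 20
generator seeds of the 16/42 preset, and the benchmark check evaluates the
full 341-model grid on 10 seeds with held-out metrics only (CV disabled)
— the per-cell CV machinery is exercised separately on small fixtures.
Statistical calibration draws 200 label permutations of a generated
cohort and checks the pooled type-I rate against 0.05 ± 0.03.

Degenerate inputs are contracts, not accidents: constant series return
zeros/NaN sentinels or raise typed errors as documented per operation;
ties in rankings break deterministically by mean rank then name; every
source of randomness flows from an explicit seed, and the pipeline driver
derives stage seeds from one global seed (values kept below 2³¹).

## Known limitations

* Metric values are convention-compatible with the major HRV packages but
  not bit-identical to any of them (Welch segmentation details, RQA radius
  reading, the CorDim window rule, and detector constants all admit
  variants; the configurable knobs expose each).
* DFA α1 inherits the standard estimator's small-box bias (see above).
* The redundancy-weighted score and the gamma index are interpretations of
  briefly-described procedures; both are pluggable.
* WFDB/EDF ingestion is out of scope; plain-text/CSV formats are the
  supported interchange.
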