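# Methods

This note documents the models, procedures and numerical choices behind
`voxpitch`: what each component computes, which parameters matter, and what
the synthetic-data machinery does and does not emulate.

## Stimulus parameter spaces

The vocal **pitch** test lives on a musical-cents scale around a 112 Hz
baseline (near the average adult-male F0). Position 1200 cents corresponds to
112 Hz exactly, and `hz = 112 * 2^((cents - 1200)/1200)`, so 100 cents is one
semitone and 1200 cents one octave. The full lattice is 1-cent steps over
(0, 2400] for each of the five vowels /a e i o u/ — 2,400 grid values per
vowel, 12,000 stimuli in total. The vocal **timbre** test scales the spectral
envelope by a dimensionless spectral-envelope ratio (SER), emulating a
vocal-tract-length change that listeners hear as speaker size; its lattice is
0.001 steps over [0.80, 1.30], i.e. 501 values per vowel. (The inclusive SER
grid gives 2,505 identifiers, not a 12,000-sound set; the two tests share the
12,000 figure only under the per-cent pitch reading, and we report the lattice
counts as computed.)

### Vowel synthesis surrogate

`synthesize_vowel` is a source–filter surrogate, not an analysis–resynthesis
system: an in-phase harmonic comb at the requested F0 is shaped by a
three-formant spectral envelope and RMS-normalised to 0.05 (relative error
< 1e-6). Formant centre frequencies and bandwidths per vowel are package
constants in the Peterson–Barney tradition for an adult male; only their
*relative* scaling by SER matters to the discrimination logic. The envelope
combines per-formant Gaussian resonances by taking the pointwise **maximum in
log amplitude**, which keeps each resonance an exact parabola on its own
basin. That choice is deliberate: the companion estimator
(`estimate_formants`) samples the spectrum at harmonics and refines peaks by
parabolic interpolation of log amplitude, which is then exact rather than
merely approximate. F0 is estimated by autocorrelation with parabolic lag
interpolation (worst-case error ≈ 0.002 Hz on the test grid).

Validity domain: formant recovery is reliable while the harmonic spacing
(= F0) does not exceed roughly 1.5× the formant bandwidth. At the 112 Hz
baseline all vowels and all SER values in [0.8, 1.3] recover centres to well
under 2%; at F0 near 224 Hz, closely spaced low formants (e.g. /o/ F1–F2) are
genuinely under-resolved — a physical sampling limit, not an implementation
artifact. A guard raises rather than aliases if a scaled formant would cross
Nyquist.

## Adaptive tracking and JND estimation

Both discrimination tests use a weighted one-up/one-down staircase
(Kaernbach). The tracked quantity is the stimulus difference Δ between the
fixed standard and the manipulated stimulus. Defaults (package constants):

| parameter | pitch | timbre | note |
|---|---|---|---|
| initial Δ | 100 cents | 12 SER-% | starting difficulty |
| phase-1 steps (up/down) | 30 / 10 cents | 3 / 1 % | coarse approach |
| phase-2 steps (up/down) | 6 / 2 cents | 0.6 / 0.2 % | fine tracking |
| phase switch | after 4 reversals | same | |
| termination | 10 further reversals | same | 14 reversals total |
| Δ floor / ceiling | 1 / 2400 cents | 0.1 / 30 % | clamping only |

With up:down = 3:1 in both phases the equilibrium satisfies
`S_up (1 - p) = S_down p`, i.e. `p = 0.75`: the track settles where the
observer is 75% correct. A reversal is a trial whose correctness differs from
the previous trial's; the recorded reversal value is the Δ presented on the
trial that completed the switch (the turning point of the track). The JND is
the arithmetic mean of Δ at the final ten reversals, and a full test averages
five runs (one per vowel). Clamping at the floor/ceiling suppresses the step,
never the correctness bookkeeping. A safety cap (default 10,000 trials) turns
pathological observers (e.g. always-correct) into explicit errors.

### Known bias of the reversal-mean estimator

The reversal mean is asymptotically centred on the 75% point (steady-state
bias ≈ +0.1 cents for a realistic observer), but the published schedule
carries a **start-up transient**: runs begin at 100 cents, far above typical
thresholds, the four coarse reversals complete at a peak (valley + 30 cents),
and the fine phase sheds that overshoot at only 2 cents/trial. The first few
of the "final ten" reversals are therefore still elevated, inflating the mean
JND by roughly 5% of the threshold (≈ +2 cents at a 40-cent threshold,
≈ +0.2 SER-% at a 4% threshold) for a logistic observer with slope 8 in
log-Δ. The transient shrinks as the psychometric function steepens
(≈ +0.4 cents at slope 32) and is shared by both test configurations.
Consumers comparing simulated JNDs against ground-truth 75% points should
expect this offset; it affects accuracy, not the reliability ordering between
observers.

## Simulated observers

2AFC observers use a logistic psychometric function in log-Δ — Weber-like
behaviour appropriate for ratio-scaled pitch differences:

    P(correct | Δ) = 0.5 + (0.5 - λ/2) · logistic(β · ln(Δ / θ))

with guess rate fixed at 0.5, inflection θ (same units as Δ), slope β
(default 8) and lapse rate λ (default 0.02), so P(0) = 0.5 and
P(∞) = 1 - λ/2. `threshold_at` inverts the function analytically;
`observer_with_p75` constructs an observer whose 75% point equals a given
JND, which is how cohort participants are turned into staircase observers
(the full pipeline then round-trips participant JND → staircase → measured
JND). A `deterministic_threshold` observer (step function at θ) supports
exact hand-checkable staircase traces.

## Emotion-recognition scoring

The 6-AFC session has 120 trials: 6 expressions × 20 words, balanced 10/10
across a female and a male speaker; chance is 1/6. `validate_design` asserts
those counts; `score_session` returns per-emotion percent correct, the pooled
total, and a 6×6 confusion matrix whose rows are response distributions
(each summing to 100%). Stimulus covariates — independent-rater emotional
intensity and F0 frequency range — are quartile-binned into four levels
("very low" … "very high") by stable rank (ties broken by table position);
the level × group analysis delegates to the mixed ANOVA. The exact published
definition of a stimulus's frequency range is not reproducible from the
available text, so both covariates are taken as input columns, not computed
from audio.

## Statistical battery

* **Pooled t / Cohen's d** from group summary statistics; d uses the pooled
  SD (with equal n, `sqrt((s1² + s2²)/2)`), which makes t and d consistent
  via `d = t·sqrt(1/n1 + 1/n2)`.
* **Mixed repeated-measures ANOVA, multivariate approach**: the
  between-subjects effect is the classical F on subject means; within and
  interaction effects are Wilks' Λ tests on the k−1 successive difference
  scores in an effect-coded multivariate linear model (error df = N − g).
  For single-degree hypotheses the exact F(k−1, N − g − k + 2) is used, i.e.
  F(5, 26) for the 2×6 design and F(3, 28) for the 2×4 level designs; Rao's
  approximation covers g > 2. Partial η² is `F·df1/(F·df1 + df2)` between
  subjects and `1 − Λ^(1/s)` multivariately; the univariate
  sphericity-assuming route is intentionally not the default because the
  multivariate df2 matches the reported design.
* **Correlations** are Pearson by default; a Shapiro–Wilk gate (α = .05 on
  either variable) switches to Spearman's ρ. p-values use the t
  approximation on n − 2 df for both methods; one-tailed p is halved only
  when the observed sign matches the pre-stated direction, else 1 − p/2.
* **Outlier screening**: Tukey fences at 1.5 × IQR with quartiles from Tukey
  hinges (default) or the SPSS-style weighted-average definition
  (`method="haverage"`).
* **Fisher's Z** compares correlations from independent samples after the
  r-to-z transform; **Steiger's Z** compares two dependent correlations
  sharing one variable, using the pooled estimate r̄ = (r12 + r13)/2 in the
  covariance correction. Both are antisymmetric by construction and are
  validated by type-I-error calibration on simulated nulls rather than
  against printed values alone (the inter-correlation needed to recompute
  the published dependent-correlation Z is not itself published).
* **Bonferroni**: significance at α/m (α = .05, m = 6 for the per-emotion
  post-hoc family, threshold ≈ .0083).

## Synthetic cohort generator

The generator emulates the matched-pair design: n pairs (default 16) matched
on gender, handedness, age (≤ 3 years within pair) and full-scale IQ (≤ 15
points within pair), constructed by drawing a pair-level centre and bounded
offsets so the constraints hold by construction. Scores are drawn from a
Gaussian copula with exactly moment-matched marginals:

* positive, right-skewed scores (pitch/timbre JNDs, ADOS communication) are
  lognormal with closed-form (μ, σ) from the target mean/SD;
* bounded percentage and questionnaire scores are logit-normal on [0, 100]
  (AQ on [0, 50]) with (μ, σ) solved by nested 1-D root finding against
  Gauss–Hermite moments (48 nodes), so samples are on the legal scale
  without clamping and means/SDs are exact in expectation.

Latent correlations are adjusted NORTA-style: for each targeted pair the
latent Gaussian correlation is solved (Brent's method over a 2-D
Gauss–Hermite integral) so the *observed-scale* Pearson correlation equals
the target despite the nonlinear marginals. The six per-emotion accuracies
share a common within-group correlation solved from the identity
`36·Var(total) = Σ s_e² + ρ Σ_{e≠f} s_e s_f` so that the variance of their
mean reproduces the target SD of the total score; each emotion carries an
equal share `c = r·6·s_T / Σ s_e` of any targeted total-score correlation
(emotion–pitchJND, emotion–AQ, emotion–ADOS). Untargeted pairs are
uncorrelated; a tiny eigenvalue clip guards quadrature round-off.

Emotion sessions are simulated per participant: correctness is Bernoulli per
trial at the participant's per-emotion accuracy, errors uniform over the
five wrong labels (a confusion-shaped kernel can be supplied instead).
Optional per-trial modulation by z-scored stimulus covariates (default in
the pipeline: +10 percentage points per SD of intensity, +5 per SD of
frequency range) produces monotone level effects of realistic strength.

What the generator does **not** emulate: item-level word effects, speaker
effects, response times, serial dependence, clinical comorbidity structure,
or any real participant's data. Passing moment-recovery tests therefore
shows that the analysis pipeline is correct under the stated joint-moment
model, not that real cohorts follow a Gaussian copula.

## Pipeline and reproducibility

`run_full_pipeline` simulates cohort → sessions → staircases → statistics
and emits the result tables (per-emotion group comparison with Bonferroni
flags, JND comparison, correlation panel with gating and outlier log,
Fisher/Steiger comparisons) plus a versioned results dictionary. All
randomness derives from one root seed split per stage with
`numpy.random.SeedSequence`, so any stage can be replayed in isolation and
two runs with the same configuration are byte-identical.
`reproduce_printed_statistics` recomputes every derivable published
statistic from the bundled reference summary values; the largest
computed-vs-printed deviation is 0.0024 (on the Fisher Z).

Problem sizes used by the verification suite and `scripts/acceptance.py`
(chosen to keep Monte-Carlo error well below the assertion tolerances while
remaining quick on a single CPU): 1,000 staircase replicates per
configuration in the test suite (600 in the script), 10,000 null datasets
per calibration of the correlation comparisons, 1,000–2,000 simulated
sessions per chance/recovery check, and pooled cohorts of 500 pairs × 100
seeds (10 in the script) for moment recovery.

## Known limitations

* The reversal-mean JND estimator carries the start-up transient described
  above; it is a property of the published schedule, reproduced on purpose.
* Formant estimation degrades when F0 approaches the formant bandwidth
  (high-pitch, closely spaced formants).
* The multivariate ANOVA requires complete data and non-singular
  difference-score covariance (k − 1 ≤ N − g); degenerate inputs raise
  rather than degrade.
* Steiger's Z uses the single pooled-r̄ variant; alternatives (e.g.
  Williams') differ slightly at small n.
* The cohort generator's copula, equicorrelated emotion block and uniform
  error kernel are modelling assumptions; only group means, SDs and the
  targeted pairwise correlations are anchored to published values.
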