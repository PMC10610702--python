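# Methods

## Problem and pipeline

The package implements an entropy-based analysis of resting-state EEG
(rs-EEG) for two-class discrimination (normal control, NC, versus a
Parkinson's-disease-like class, PD), together with an entropy-trajectory
monitoring view.  The pipeline is:

1. **Acquisition / simulation** — 14-channel records (10–20 montage
   AF3…AF4) at 128 Hz in microvolts, ~5 min per subject.  Because clinical
   recordings of this kind are private, a seeded generator produces
   synthetic two-class cohorts (below).
2. **Preprocessing** — 5th-order Butterworth band-pass 0.5–32 Hz applied
   zero-phase (forward–backward), division into non-overlapping contiguous
   segments of `L_EEG` samples (protocol range 150–1000), and rejection of
   any segment containing a sample with |x| strictly above 85 µV.
3. **Subband variants** — per channel and segment, a 4-level db4 DWT with
   symmetric extension; nine signals: the original O plus cA1–cA4 and
   cD1–cD4, each reconstructed from a single coefficient vector (all others
   zeroed).  Nominal bands at 128 Hz: cA1 0–32, cA2 0–16, cA3 0–8, cA4 0–4,
   cD1 32–64, cD2 16–32, cD3 8–16, cD4 4–8 Hz.
4. **Entropy features** — seven estimators (SVDEn, PermEn, SampEn, CoSiEn,
   FuzzyEn, PhaseEn, AttnEn) on each (channel, variant) series; 14 × 9 = 126
   features per segment for one hyperparameter configuration.
5. **Classification** — a support-vector classifier assessed with a
   two-stage repeated stratified K-fold protocol: stage 1 (K = 10 folds,
   N₁ = 10 repeats) selects SVC hyperparameters by mean validation accuracy;
   stage 2 re-evaluates the chosen setting on N₂ = 30 fresh partitions from
   a disjoint seed stream.  A_RKF is the mean validation accuracy over the
   stage-2 folds; E_RKF = 1 − A_RKF.
6. **Feature reduction** — greedy forward selection on A_RKF, reporting the
   accuracy-versus-feature-count curve and the smallest set within a
   tolerance of the full-feature accuracy.
7. **Monitoring** — per-visit mean entropy of one chosen (channel, variant)
   feature plotted against class reference histograms with shared bin
   edges; the increase/decrease flag is descriptive, not diagnostic.

## Entropy estimators: conventions that matter

All "×std" tolerances use the population standard deviation of the analysed
series itself (computed per segment per variant), so the tolerance adapts to
each subband signal.

* **SVDEn** uses base-2 logarithms in both the Shannon sum and the
  normalization by log2(m), giving a true [0, 1] range.  Singular values
  below the standard numerical-rank tolerance are treated as zero so
  rank-deficient embeddings (e.g. a constant series) give exactly 0.
* **PermEn** breaks rank ties by stable index order; normalized by
  log2(m!).
* **SampEn** follows the Richman–Moorman convention: the first N−m length-m
  templates enter both C(m, r) and C(m+1, r), self-matches excluded, with
  Chebyshev distance and an inclusive (≤ r·std) threshold.  This makes the
  constant series evaluate to exactly 0.  A zero count at either dimension
  is *undefined*: the estimator returns NaN with a warning and the feature
  assembly refuses to build a matrix containing it — undefined entropies
  are never imputed.
* **CoSiEn** measures angular distance as (1/π)·arccos of the cosine
  similarity (clamped to [−1, 1]); the printed similarity-based formula in
  common write-ups is not a metric.  B is the proportion of template pairs
  within tolerance; the output is the binary Shannon entropy of B, with the
  endpoints B ∈ {0, 1} defined as 0.  Zero-norm templates are excluded.
* **FuzzyEn** mean-centres templates and uses the membership
  D = exp(−d^r2 / (r·std)); φ at each dimension averages D over all ordered
  pairs of the actually constructed templates (N−m+1 at dimension m), which
  sidesteps the off-by-one ambiguity of textbook denominators.  Note the
  measure is scale-free only for r2 = 1; for r2 > 1 absolute amplitude
  enters through d^r2/σ, which is deliberate — amplitude differences are
  informative in this analysis.
* **PhaseEn** sums the slope angles θ = atan2(Y, W) ∈ [0, 2π) of the
  second-order difference plot within K equal sectors and takes the
  normalized Shannon entropy of the resulting mass distribution (the ratio
  is log-base invariant).  All-zero angle mass is defined as 0 with a
  warning.
* **AttnEn** detects strict local extrema, builds the four interval sets
  (max–max, min–min, max–min, min–max), and averages their natural-log
  Shannon entropies over interval-length frequencies; an empty set
  contributes 0.  Monotone series (no extrema) are degenerate inputs.

Hyperparameter grids: SVDEn/PermEn m = 2…10 (delay 1); SampEn m = 1…3 with
r = 0.05…0.5×std in steps of 0.05; CoSiEn m = 2…3, r = 0.05…0.5 absolute;
FuzzyEn m = 1…2, r = 0.05…0.5×std, r2 = 1…5; PhaseEn K = 2…10; AttnEn has no
parameters.  The 0.05 lattice is chosen so that the commonly reported
optimum r = 0.15 lies on it.  The flagship configuration throughout the
experiments is FuzzyEn(m = 1, r = 0.15×std, r2 = 5).

## Synthetic cohort generator

Each channel is a per-band mixture of

* band-limited Gaussian noise — white noise through a 4th-order Butterworth
  band-pass for the band (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30,
  gamma 30–49 Hz), and
* a *narrowband quasi-sinusoidal oscillation* — noise through a 2nd-order
  band-pass of ±10% around the band-centre frequency, i.e. a rhythm whose
  phase and envelope drift naturally.

The `irregularity` dial in [0, 1] (scalar or per-band) sets the
noise/oscillation power split per band; `band_powers` the relative band
powers (normalized to 1); `amplitude_uV` the channel standard deviation.
Artifacts are injected separately as raised-cosine pulses (≤0.25 s, chosen
peak amplitude, random sign/channel) at Poisson-distributed times.

**Why not pure sinusoids?**  At 128 Hz every band-centre frequency is a
rational multiple of the sampling rate, so a pure sampled sinusoid repeats
exactly on a ≤512-sample lattice; the subject's random phase then fixes a
sampled pattern that is *identical in every segment of that subject*.  In
development this made FuzzyEn of cD2 a near-perfect subject fingerprint
(intraclass correlation 0.96) and pushed an identical-profile null cohort to
A_RKF ≈ 0.77 under segment-level cross-validation — manufactured accuracy
from subject identification, not class structure.  The drifting narrowband
oscillation removes this artifact while preserving the rhythmic/irregular
dichotomy the entropy features measure.

**Default class profiles.**  The default NC/PD profiles concentrate the
class effect in the low frequencies so that the delta-dominant structure is
recoverable by the per-variant analysis: PD has ~2.6× NC's absolute delta
power (relative powers 0.351 vs 0.18 at amplitudes 17.22 vs 15 µV — the
amplitudes are set so the *absolute* alpha/beta/gamma power is matched
between classes), delta irregularity 0.85 vs 0.15, and a mild theta bump
(+15% power, irregularity 0.45 vs 0.30).  Amplitudes sit far below the
85 µV artifact threshold so clean records survive rejection.

**What the generator does not emulate**, and what passing tests therefore do
not show about clinical data: no 1/f background, no neural-mass or volume-
conduction structure (channels are independent), no non-stationarity beyond
the oscillators' natural drift, no ocular/muscle artifact waveforms (only
generic amplitude transients), and no physiological link between the PD
label and any disease process.  Within-class, between-subject entropy
variance in real cohorts is unknown; here it is whatever the generator's
sampling variability produces, so synthetic effect sizes say nothing about
clinical effect sizes.  The raw-signal entropy footprint of the
irregularity dial is strongest when power is concentrated in one band; in
broadband mixtures it is diluted and resolves only after subband
decomposition — which is exactly the analysis' rationale for the DWT stage.

## Cross-validation protocol

Stage-1 and stage-2 partitions come from disjoint seed streams (distinct
seeds are enforced).  Folds are class-stratified.  Features are z-scored
inside each fold with statistics fitted on the training folds only; scaler
and SVC live in one sklearn Pipeline, so standardization cannot see
validation data (a canary test perturbs validation rows and asserts the
fitted statistics are unchanged).  The SVC grid is deliberately compact —
kernel ∈ {linear, RBF}, C ∈ {0.1, 1, 10, 100}, RBF width ∈ {scale, 0.01,
0.1} — ordered simplest-first (linear before RBF, small C first) so exact
score ties resolve toward parsimony.

`split_unit='segment'` mirrors the reference protocol, where the five
segments of one subject are independent observations and may straddle
train/validation.  This is a known optimism source whenever segments of one
subject correlate; `split_unit='subject'` (grouped stratification) is
provided and recommended for honest subject-level claims.  The generator
work above keeps the synthetic null honest even at segment level, but real
data offer no such guarantee.

Greedy forward selection evaluates candidate sets on a reduced protocol
(N₂ = 5) for tractability — the search is O(F²) cross-validation runs — and
re-evaluates the reported curve at the full protocol.  Ties break by
lexicographic feature name.  SVC hyperparameters are selected once on the
full feature set and reused across subsets (a flag allows re-selection).

## Problem sizes

Protocol-scale runs (acceptance script, heavyweight tests) use 20+20
subjects, 300 s records, five segments of L_EEG = 1000 samples (200
observations × 126 features); these sizes make a full matrix build plus
two-stage evaluation take a few minutes.  Unit tests use 3–8 subjects per
class, 8–16 s records and L_EEG = 150–256, which exercise every code path
at negligible cost.  Experiment rankings use competition ranking (1 +
number of strictly greater scores) so conditions tied at ceiling share rank
1 rather than receiving an arbitrary order.

## Numerical choices and degenerate inputs

* Zero-phase filtering doubles the effective magnitude order of the
  Butterworth response; filter contracts are asserted against the analytic
  squared magnitude response away from edge transients.
* Wavelet reconstructions are cropped to the source length; symmetric
  half-sample extension preserves perfect reconstruction, which the tests
  assert at 1e−8 relative.  The 0.5–32 Hz pre-filter attenuates the nominal
  cD1 (32–64 Hz) band, so cD1 carries roll-off residue; it is still
  computed because downstream analyses enumerate all nine variants.
* A sample exactly at the 85 µV threshold is kept (strict inequality).
* Segments are taken from the start of the usable (artifact-free) signal;
  segmentation is deterministic and seed-free.
* All CLI writers use canonical JSON (sorted keys) and fixed float formats;
  re-running any subcommand with identical seeds reproduces outputs byte
  for byte.

## Known limitations

* EDF export is not provided (no writer backend among the supported
  dependencies); cohorts interchange as per-subject CSV plus JSON sidecar.
  EDF *reading* through MNE is available but untested here.
* The segment-level protocol's optimism on correlated segments is inherent;
  see the split-unit discussion above.
* CoSiEn/PhaseEn normalizations assume at least two occupied states; inputs
  engineered to degenerate cases return 0 with a warning or raise, as
  documented per estimator.
* The generator's independence across channels means channel-level analyses
  see no volume-conduction leakage; real montages would.
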