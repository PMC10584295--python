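# Methods

`refluxion` reimplements a machine-learning system for identifying
gastroesophageal reflux events in 24-hour multichannel intraluminal
impedance/pH (MII-pH) recordings, together with the adjudicated
gold-standard evaluation framework such systems are judged by. Because
real MII-pH studies cannot be redistributed, the package ships a
calibrated synthetic-study generator and runs the entire pipeline —
candidate detection, clip classification, reader adjudication, matched
metric evaluation — on ground-truthed simulations.

## The pipeline

A recording carries six impedance channels ordered distal→proximal
(channels 1–2 distal, 3–6 proximal) and two pH channels (channel 1
distal). A liquid bolus lowers impedance; a **reflux event** is a
retrograde drop (distal channels fall first, the drop propagates
proximally across ≥ 2 adjacent sensors), while a **swallow** is the
antegrade mirror image and a single-sensor transient is an artifact.

1. **Meal exclusion.** Patient-marked meal intervals are removed from
   analysis entirely; no candidate or clip may intersect one.
2. **Baseline estimation.** Per-channel baselines are centered
   rolling medians. The default window is 300 s: long events (up to
   30 s) must occupy a small minority of the window or the median tracks
   the drop and the relative threshold chases it (a 60 s window fails
   exactly this way for 30 s events, which is why the default is
   longer). Edges use truncated windows. Studies whose distal baseline
   medians below 750 Ω over non-meal time are flagged and excluded,
   mirroring clinical practice of not over-reading low-impedance studies.
3. **Candidate detection.** A deliberately permissive, direction-agnostic
   peak finder: any maximal interval where ≥ 2 adjacent channels sit
   simultaneously below 50% of their local baseline for ≥ 3 s (runs
   separated by < 5 s merged first) becomes a candidate. Swallows and
   multi-channel artifacts *are* candidates by design; the detector's
   contract is sensitivity (≥ 95% recall of true events on default
   synthetic cohorts), and discrimination is delegated to the
   classifier. All thresholds are baseline-relative, so the candidate
   set is invariant under uniform scaling of the impedance values.
4. **Clip extraction.** One 60-second window per candidate, centered on
   the candidate onset (shifted inward at recording edges), each channel
   normalized by its local baseline so values are fractions of baseline.
   A clip is labeled positive iff a ground-truth event onset falls
   inside the window within ±5 s of the candidate onset. A fixed-tiling
   mode (stride 60 s) exists for ablation; candidate-centered is the
   default because it gives an unambiguous clip↔event correspondence.
5. **Classification** (below), producing a per-clip reflux probability.
6. **Evaluation** on an adjudicated gold universe (below).

## The structured state-space classifier

Each layer is a bank of independent diagonal continuous-time linear
state-space systems, one per model feature:

    x'(t) = A x(t) + B u(t),   y(t) = 2 Re(C x(t)) + D u(t),   Re(A) < 0

discretized by zero-order hold at per-feature step Δ (exact for diagonal
systems): Ā = exp(ΔA), B̄ = (Ā − 1)/A · B. The layer can be evaluated
either as a recurrence x_t = Ā x_{t−1} + B̄ u_t or as one long causal
convolution with kernel k[i] = 2 Re(Σ_n C_n Ā_nⁱ B̄_n); the two are
mathematically identical, and their numerical agreement (≤ 1e−4 up to
L = 3000) is the central correctness test of the implementation.

Architecture: linear encoder 6 → d_model (default 32); two SSM blocks
(FFT convolution + skip term D·u, GELU, residual); mean pooling over
time; logistic head. State size d_state = 16 per feature.

Parameterization and training:

* **A, B, Δ are frozen** at a structured long-memory initialization —
  A_n = −1/2 + iπn (a diagonal-approximation initialization), B = 1, Δ
  log-spaced per feature from 1e−3 to 1e−1 (kernel decay lengths ~20 to
  ~2000 samples, bracketing the 600-sample clips). **C, D, encoder and
  head are trained.** With the dynamics frozen, each kernel is a linear
  combination of fixed damped-oscillation basis functions, which keeps
  the hand-derived numpy backpropagation exact and compact while
  preserving the long-range convolution mechanism. The `discretize`,
  `ssm_kernel` and recurrence primitives support the full
  parameterization regardless.
* Loss: class-weighted binary cross-entropy, weight = (#neg/#pos) of the
  training split (candidate pools are negative-heavy: detected swallows
  outnumber reflux events roughly 8:1 at default rates).
* Optimizer: Adam, lr 0.01, batch 64, ≤ 20 epochs; the parameter
  snapshot with the best validation AUC is returned. Training runs in
  single precision (deterministic; returned parameters are promoted to
  float64). Splits must be disjoint by study id — patient leakage is a
  hard error, not a warning.
* Gradients are analytic (derived by hand through the FFT convolution,
  GELU, residual and pooling) and verified against central finite
  differences to 1e−3 relative on a small model.
* Inference is deterministic (dropout, off by default, is disabled);
  models serialize to a plain JSON container of real/imaginary arrays.

Input features are the six baseline-normalized impedance channels only;
pH is not a model input (acid/nonacid subtyping is out of scope).

A deliberately simple logistic-regression baseline over hand-crafted
clip summaries (per-channel minima, time-of-minimum ordering, time below
the 50% criterion) lives in `refluxion.baseline` as a sanity reference;
it is not part of the system.

## Gold standard and metrics

The evaluation copies the two-reader adjudication design. Two simulated
readers independently mark each study; marks concordant within ±5 s are
reflux events; discordant marks go to a tiebreaker (a third reader, or
the ground truth as a perfect oracle in simulation): confirmed →
positive, rejected → adjudicated nonevent. The negative class is then
extended with detector candidates matching no positive. The evaluation
universe is **positives ∪ these hard negatives only** — unmarked quiet
time contributes nothing. This deliberately narrow negative pool avoids
swamping the metrics with trivial negatives and makes specificity a
demanding statistic; it also means reported specificity is *not*
comparable to per-minute false-alarm rates.

Metrics, all computed on that universe:

* **AUC** as the Mann–Whitney statistic (midranks for ties), with a
  percentile bootstrap CI from 1,000 repetitions resampling the pooled
  records (single-class resamples redrawn). Resampling is event-level,
  not patient-level.
* **Matched-threshold sensitivity/specificity**: the simulated expert
  reader's empirical (FPR, TPR) on the universe is found by event
  matching; the model's sensitivity is its TPR at the smallest threshold
  with FPR ≤ the expert's FPR, and its specificity the TNR at the
  largest threshold with TPR ≥ the expert's TPR (classification is
  score ≥ threshold; both agree with exhaustive threshold enumeration
  by construction and by test). The expert reader is reported as an
  operating point, never as a curve.
* **Cohen's kappa** between the two readers over the universe,
  κ = (p_o − p_e)/(1 − p_e), degenerate marginals defined as 0 with a
  warning.
* Event matching is greedy nearest-onset one-to-one within ±5 s, ties
  broken toward the earlier onset — deterministic and equal to the
  iterated closest-admissible-pair oracle.
* Gold records with no matching scored candidate are scored 0: a
  detector miss is charged to the system, so end-to-end sensitivity
  reflects the whole pipeline, not the classifier alone.

## The synthetic-study generator

The generator emulates the statistical structure the pipeline relies
on, calibrated to the cohort it stands in for:

* Per-study event counts: zero-truncated Gaussian, test-set calibration
  mean 45.3, SD 23.6 per 24 h (training calibration 51.2 (33.0)),
  pro-rated to the study duration and rounded. The truncation bias at
  these parameters (≈ +1.5 events/24 h) is small against the ±2 SE
  calibration band.
* Acid exposure: a configured fraction of events also pull distal pH
  below 4; per-event acid hold times are allocated by waterfilling so
  the realized percent of non-meal time at pH < 4 matches the study's
  target. Cohorts draw per-study targets from a Gamma with mean 3.1%,
  SD 3.0% (test calibration) — Gamma because the quantity is
  nonnegative and right-skewed and the first two moments are then exact.
* Morphology: multiplicative drops to (1 − 0.7) × baseline on 2–6
  adjacent channels, retrograde per-channel lag 0.5 s, 2 s linear fall,
  plateau, exponential recovery (τ = 2 s), durations 10–30 s. Swallows:
  all six channels, antegrade lag 0.3 s, depth 0.6, durations 5–10 s —
  deep and long enough to trip the candidate detector, which is what
  makes them hard negatives. Artifacts: single-channel drops (depth
  0.8, 2–5 s) that a ≥ 2-adjacent-channel detector must ignore. Event
  amplitude/duration statistics for the real cohort are not published;
  these are documented conventions, not estimates.
* Baselines ~2000 Ω (SD 200 across channels), slow sinusoidal drift
  (100 Ω, 1 h period), white noise SD 50 Ω, elevated noise during
  meals. Default meal schedule: three 20-minute meals at 25/55/85% of
  the recording.
* Placement keeps every drop ≥ 45 s from meals and from other drops, so
  ground-truth labels are unambiguous and candidate-centered clips
  never touch a meal. This is a simplification: real swallows cluster
  (especially around meals) and real events can overlap swallows.
* Readers: each true event is marked with probability `hit_rate`
  (default 0.8) under Gaussian onset jitter (SD 1.5 s); false marks
  (default 36/24 h) land uniformly on non-meal, non-event time.
  Defaults were chosen so the simulated expert's operating point and
  the inter-reader kappa land near the reference report (TPR ≈ 0.8,
  FPR ≈ 8–13% of the negative pool, κ ≈ 0.3–0.4).

Everything is a pure function of (config, seed); cohorts derive
per-study seeds from a `SeedSequence`, and the benchmark fans a single
global seed out to every stage.

**What passing on synthetic data does and does not show.** The
generator's events are cleanly separated, stereotyped, and noise is
stationary and Gaussian; real recordings have overlapping events,
nonstationary baselines (catheter movement, mucosal contact), gas
reflux, and reader behavior far richer than a (hit-rate, false-rate,
jitter) triple. Benchmark numbers on this simulator therefore validate
the *implementation and the evaluation machinery* — that the system can
learn retrograde-vs-antegrade discrimination end-to-end and that every
statistic is computed correctly — not clinical performance. They sit
above the published clinical figures precisely because the synthetic
task is cleaner than the clinical one.

## Benchmark scale and numerical choices

The default benchmark is desk-scale: 20/5/20 studies of 4 simulated
hours at 10 Hz, with per-24 h rates applied pro rata; a full run
(simulate → detect → train → adjudicate → evaluate) takes a few minutes
on one CPU. 24-hour studies and other rates are supported by
configuration.

* Time is seconds from recording start; intervals are half-open.
* Rolling-median windows are rounded to an odd sample count.
* FFT convolutions pad to `next_fast_len(2L)`, so circular wrap never
  touches the causal range.
* Matching tolerance is ±5 s everywhere (labeling, adjudication,
  scoring, expert operating point): larger than reader jitter and
  detector onset offset (~1.4 s, the time the fall needs to cross the
  50% criterion), far smaller than the enforced inter-event spacing.
* The bootstrap redraws single-class resamples (the pooled-resampling
  reading of the reference procedure); a stratified mode is not
  provided because the pooled universe is never single-class in
  practice.
* Degenerate inputs fail loudly: single-class splits, study-id leakage
  between splits, meals covering the whole recording, unresolvable
  discordant marks, pH outside [0, 14].

## Known limitations

* Acid/nonacid event subtyping, pH-only detection, symptom association
  indices, and comparisons against commercial analysis software are out
  of scope.
* The frozen-dynamics parameterization trades some capacity for
  simplicity; it is sufficient for this discrimination task but is a
  deliberate simplification of fully-trained state-space models.
* The expert reader is a simulation; its operating point is an emergent
  property of the reader model and the negative pool, parameterized
  rather than hard-coded.
* Specificity is defined against the narrowed nonevent pool and should
  not be read as a clinical false-alarm rate.
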