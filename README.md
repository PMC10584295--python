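# refluxion

Identification of gastroesophageal reflux events in 24-hour esophageal
pH/impedance (MII-pH) studies.

Interpreting a 24-hour MII-pH recording means finding every reflux
event — a retrograde impedance drop propagating from the distal to the
proximal sensors of a 6-channel catheter — among thousands of swallows,
artifacts and meals. Manual review is slow and inter-reader agreement
is modest, and commercial auto-analysis is notoriously unspecific.
`refluxion` implements a complete machine-learning identification
system and, just as importantly, the adjudicated evaluation framework
such systems are judged by:

* **Signal-processing front end** — meal exclusion, rolling-median
  baselines, a permissive multi-channel peak-finding candidate
  detector, and 60-second baseline-normalized clip extraction.
* **Structured state-space (S4-style) clip classifier** — each layer is
  a bank of diagonal continuous-time linear systems x' = Ax + Bu,
  y = 2 Re(Cx) + Du, ZOH-discretized (Ā = e^{ΔA}, B̄ = (Ā−1)/A·B) and
  evaluated as one long causal convolution with kernel
  k[i] = 2 Re(Σₙ Cₙ Āₙⁱ B̄ₙ); a pure-numpy implementation with
  hand-derived analytic gradients, trained by Adam on class-weighted
  cross-entropy. Convolutional and recurrent evaluations are verified
  against each other — the defining numerical identity of these models.
* **Gold-standard evaluation** — two-reader adjudication with a
  third-reader tiebreak, a deliberately narrow hard-negative
  ("nonevent") pool, Mann–Whitney AUC with a 1,000-repetition
  percentile bootstrap CI, sensitivity at the expert reader's false
  positive rate, specificity at the expert's true positive rate, and
  Cohen's kappa for inter-reader agreement.
* **Calibrated synthetic cohorts** — ground-truthed simulated studies
  (retrograde reflux drops, antegrade swallows, artifacts, meals, acid
  exposure realized to target) matching published per-study event-count
  and acid-exposure statistics, plus simulated imperfect readers. Real
  recordings are not redistributable; the whole pipeline runs end to
  end on these simulations.

See `docs/methods.md` for the model, the generator, and every numerical
convention.

## Worked example

Run the full default benchmark — 20 training / 5 validation / 20 test
synthetic studies of 4 simulated hours at 10 Hz, detector, classifier
(2 layers, d_model 32, d_state 16, ≤ 20 epochs), two simulated readers,
adjudication, evaluation — from Python:

```python
from refluxion import RunConfig, run_benchmark

report, manifest = run_benchmark(RunConfig(global_seed=1))
print(report.summary())
```

which prints (a few minutes on one CPU):

```
Reflux event identification — evaluation report
========================================================
gold universe: 148 events, 1428 nonevents
AUC: 0.977  (95% CI 0.956-0.995)
sensitivity 98.0% at matched FPR 7.9%
specificity 99.1% at matched TPR 85.1%
inter-reader Cohen's kappa: 0.31
```

Reading the numbers: the adjudicated test universe holds 148 reflux
events and 1,428 hard negatives (adjudicated nonevents plus unmatched
detector candidates — swallow-like drops, not quiet time). The
classifier separates them with AUC 0.977; at the decision threshold
whose false positive rate matches the simulated expert reader's (7.9%),
it recovers 98.0% of events; at the threshold matching the expert's
sensitivity (85.1%), it rejects 99.1% of nonevents. The two simulated
readers agree at κ ≈ 0.31 — deliberately imperfect, which is what the
adjudication machinery is for. (Synthetic events are cleaner than
clinical ones, so these figures sit above published clinical
performance; see `docs/methods.md` on what they do and do not show.)

The same run from the shell:

```bash
refluxion run --seed 1 --out results/
```

writes `report.json`, `manifest.json` (seeds, config hash, per-stage
counts — enough to reproduce the run bit for bit), `model.json`,
`test_scores.csv` and an ROC curve. The individual stages are exposed
as `refluxion simulate / detect / clips / train / predict / evaluate`,
all reading and writing plain-text formats (TSV studies, CSV
annotations and event lists; see module docstrings in
`refluxion.io`).

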