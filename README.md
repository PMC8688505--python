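# microdyn

EEG microstate dynamics for open-ended design tasks: task-related band
power, polarity-invariant microstate segmentation, and temporal statistics
of microstate label sequences — implemented as a tested analysis pipeline
exercised end-to-end on synthetic EEG with planted ground truth.

## The scientific problem

During an open-ended creation task (understanding a design problem,
generating ideas, evaluating them, rating one's own effort) the brain moves
through a sequence of large-scale network configurations.  Scalp EEG makes
two complementary views of this accessible:

* **Task-related power (TRP)** — per channel *i*, the log band-power change
  from an eyes-closed rest baseline,
  `TRP_i = log10(Pow_i,task) − log10(Pow_i,rest)`,
  with canonical bands delta 1–3.5, theta 4–7.5, alpha 8–13.5 and beta
  14–29 Hz.  Negative alpha TRP (event-related desynchronization) indexes
  cognitive workload; theta/beta changes index cognitive control.

* **EEG microstates** — brief periods (tens of ms) during which the scalp
  topography stays quasi-stable.  The topographies at peaks of the global
  field power (GFP, the per-sample SD of potentials across electrodes) are
  clustered by a polarity-invariant *modified k-means*: each sample is
  assigned to the unit-norm template Γ_k maximizing the squared spatial
  projection, templates are updated as dominant eigenvectors, and the cost

  `F = 1/(N_T (N_S−1)) · Σ_t ‖V_t − a_kt Γ_k‖²`

  is minimized; the cluster count is selected by the cross-validation
  criterion `CV = σ̂² · ((N_S−1)/(N_S−1−N_K))²`.  Back-fitting every sample
  to the template with the highest absolute spatial correlation (no
  temporal smoothing) yields a categorical label sequence per run.

The temporal structure of that label sequence is quantified on three time
scales: the **finite entropy rate** `h(k) = H(X^(k+1)) − H(X^(k))`
(bits/sample, history k = 6), the **autoinformation function**
`I(τ) = H(X_{t+τ}) + H(X_t) − H(X_t, X_{t+τ})` with its first-peak
latency, and the long-range **Hurst exponent** from detrended fluctuation
analysis of the sequence mapped to ±1, averaged over all 35 {3,4}
bipartitions of the 7 microstate classes.  Less constrained processing
(e.g. idea generation) shows up as a higher entropy rate and a Hurst
exponent closer to 0.5.

## Layout

* `src/microdyn/` — the library: `synth` (synthetic EEG and sequences with
  planted dynamics), `preprocess` (filtering, QC, interpolation,
  re-referencing), `trp` (Welch band power and TRP), `microstates`
  (modified k-means, back-fitting, parameters), `seqstats` (entropy rate,
  AIF, DFA), `stats` (repeated-measures ANOVA with Greenhouse–Geisser
  correction), `pipeline` (cohort orchestration), `io` (BrainVision/EDF
  readers, plain-text fixture format).
* `analysis/` — numbered drivers, one per analysis stage, writing their
  tables under `results/`.
* `tests/` — unit, property and end-to-end acceptance tests.

## Worked example

`python analysis/05_sequence_dynamics.py` checks the sequence statistics
against analytic oracles:

```
Markov chain entropy rate: plug-in 2.2595 vs analytic 2.2595 bits/sample
AIF identity: I(0) = 2.7058 = H(X) = 2.7058 bits
DFA on sign-thresholded fGn (H=0.5): mean estimate 0.510 over 10 seeds
DFA on sign-thresholded fGn (H=0.7): mean estimate 0.683 over 10 seeds
```

The plug-in entropy rate of a simulated 7-state Markov chain matches the
closed-form rate to three decimals; DFA recovers the planted Hurst
exponent of sign-thresholded fractional Gaussian noise within ±0.02–0.05.

`python analysis/06_cohort_report.py` runs the whole chain on a synthetic
5-participant cohort in which idea generation (IG) was planted with the
most random switching:

```
Entropy-rate condition ANOVA:
   effect      F  df1_gg  df2_gg      p  partial_eta_sq
condition 22.302  2.1804  8.7214 0.0003          0.8479

IG entropy rate 0.898 bits/sample is the cohort maximum: True
IG mean Hurst 0.858 is the cohort minimum: True
```

i.e. the pipeline recovers, from raw synthetic EEG through preprocessing,
clustering and back-fitting, the planted contrast: highest entropy rate
and lowest long-range memory during idea generation.

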