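# Methods

## Scope and model

`ecgtriage` models prehospital STEMI screening as a binary scoring problem
on the standard 12-lead ECG. The classifier chain is: 156 morphological
measurements → standardization → PCA (20 components) → per-component
Z-scores → a bagged ensemble of 25 single-hidden-layer perceptrons → a
score in (0, 1) → a sensitivity-anchored decision threshold. Two outcomes
are supported, STEMI on ECG criteria and the need of acute PCI; both are
generator-assigned ground truth, never re-derived from the classifier.

## Synthetic cohort generator

Because no ambulance waveform set ships with the package, cohorts are
simulated. Each beat is a sum of five Gaussians (P, Q, R, S, T) on the eight
electrically independent leads (I, II, V1–V6); III, aVR, aVL and aVF are
recomputed from I and II through the Einthoven/Goldberger relations, so the
limb-lead identities hold to machine precision on every record — including
after ST injection, which perturbs I and II and re-derives the rest.
Inferior-territory elevation uses dI = −m, dII = +m, which yields III = +2m,
aVF = +1.5m and a reciprocal aVL depression, as in real inferior infarcts.

Defaults (all configurable in `SynthConfig`):

| parameter | default | rationale |
|---|---|---|
| sampling rate / duration | 500 Hz, 10 s | typical clinical recorder settings |
| heart rate | 60 bpm ± 3% per record | keeps a whole T wave inside each beat |
| ST magnitude | U(0.15, 0.40) mV, floored at threshold + 0.05 mV | guarantees injected cases satisfy the diagnostic rule (2 mm in V1–V3, 1 mm elsewhere; 1 mm = 0.1 mV) |
| taper | 20 ms raised cosine each side of the J→T-end plateau | avoids step discontinuities |
| noise | 0.02 mV white | light electrode noise |
| baseline wander | 0.05 mV at 0.33 Hz, random phase per lead | respiration-band drift |
| amplitude jitter | 10% s.d. per wave/lead/record | inter-patient variability; prevents degenerate (constant-column) feature matrices |
| prevalence | STEMI 38/560; P(PCI│STEMI) = 0.9, P(PCI│no STEMI) = 0.01 | ambulance chest-pain population with nearly overlapping STEMI and acute-PCI groups |

A proximal-limb-placement perturbation (`limb_gain`, `limb_offset`) is
available for test cohorts and off by default.

What the generator does **not** emulate: realistic P/T morphology and its
disease variants, arrhythmias, bundle branch block (left BBB belongs to the
clinical STEMI definition but has no waveform model here and is excluded),
ST depression without elevation, electrode artifacts, pacing. Consequently a
passing signal-recovery suite shows the pipeline is correctly wired and can
learn the injected ST signal; it does not estimate performance on real
ambulance ECGs, where the morphological overlap between classes is far
larger. The near-perfect AUROC on synthetic cohorts should be read that way.

## Feature extraction

Fiducials are global per record, detected on the cross-lead RMS signal
(5-sample moving-average smoothed): R peaks are RMS maxima ≥ 0.2 mV at
least 0.4 s apart; QRS bounds are found by scanning outward from the R peak
until |d(RMS)/dt| stays below 10% of its beat maximum for ≥ 8 ms; T end is
the first return of the RMS to within 0.05 mV of its PR-window baseline
after the T peak. Beats lacking a complete PR window (40 ms ending 10 ms
before QRS onset) or T wave are dropped; a record with no complete beat
raises a detection error. Global fiducials are more robust than per-lead
detection when single leads are noisy; the trade-off is that QRS duration
becomes a record-level quantity repeated in each lead block.

All 13 per-lead measures are baseline-relative (per-lead PR-window mean) and
averaged over beats. The six ST positions J + {0, 16, 32, 48, 64, 80} ms are
equally spaced J-anchored samples covering the clinically read ST segment;
samples falling past the T end or the record end are clipped to the last
valid sample with a logged warning. The adjacency rule for the ST-elevation
criterion pairs consecutive precordials and any two leads within the groups
{II, III, aVF}, {I, aVL} and {V5, V6, I, aVL}.

## Reduction

Features are standardized before PCA because the 156 measures mix mV, ms
and mV·ms scales; unscaled PCA would be dominated by the area and duration
columns. The 20 component scores are then Z-scored with training-set means
and standard deviations (population, ddof = 0). Component signs are fixed so
each loading's largest-magnitude entry is positive, making fits
reproducible. Constant feature columns get unit standard deviation with a
warning (they carry no variance and vanish after centering). Application to
new data is a pure function of the stored parameters.

## Ensemble training

Each member is initialized uniformly in [−0.1, 0.1] from its own derived
seed and trained by full-batch gradient descent for a fixed number of epochs
(default 400, learning rate 0.5) on its own bootstrap resample (size equal
to the training set; resamples missing a class are redrawn). The update
direction is the gradient of the *mean* per-sample objective, so the
learning-rate default does not depend on the batch size; the summed loss and
its analytic gradient are exposed directly and are verified against central
finite differences in the tests. The weight-elimination penalty uses
w₀ = 1, natural on Z-scored inputs: weights well below 1 are shrunk
ridge-like, weights above 1 cost at most λ each. Biases are excluded from
the penalty.

Cross-validation (stratified k-fold, default 5) trains a single network per
fold and grid point and selects the (λ, hidden-size) pair with the highest
mean held-out AUROC; exact ties break toward larger λ, then fewer hidden
nodes. A single network per fold keeps the search tractable; bagging mainly
reduces variance, so member-level AUROC ranks the grid adequately.

## Evaluation

A case is called positive at score ≥ threshold (closed lower bound fixes tie
behavior). `threshold_at_sensitivity` returns the largest threshold whose
sensitivity meets the target, which maximizes specificity under the
constraint; with n⁺ positives the achieved sensitivity is ⌈target·n⁺⌉/n⁺ or
higher under ties. AUROC is computed by the rank formula (Mann–Whitney with
half-credit ties), identical to the trapezoidal area. Its interval is a
stratified-bootstrap percentile interval (default 2000 replicates, seeded;
widened if needed to contain the point estimate). Proportions use exact
Clopper–Pearson intervals via beta-quantile inversion, applied to PPV and
NPV as well as sensitivity and specificity. Serial combination ANDs the
screen and confirmatory calls, modeling a workflow where screen-negative
ECGs are never transmitted.

The pipeline calibrates the operating threshold on the training cohort by
default, avoiding test-set leakage; anchoring on the evaluation cohort
itself (as a study analyzing a single fixed cohort would) is available via
`threshold_cohort="test"`.

## Problem sizes and numerical choices

The heaviest check, full-pipeline signal recovery, trains on a 3000-case
synthetic cohort and evaluates on 560 cases (≈ 40 s on one CPU); unit-level
ensemble tests use reduced member counts and epochs since they probe
contracts, not asymptotics. Coverage of the exact intervals is verified on a
p × n grid with 20,000 binomial replicates per point: the worst-case true
coverage on that grid is 95.6%, so the Monte-Carlo error must sit well under
0.6% for a strict ≥ 95% assertion to be stable. Network outputs are clipped
to [1e−12, 1 − 1e−12] before logs; gradient checks use h = 1e−6 with 1e−5
relative tolerance.

## Known limitations

- The generator's class separation is optimistic by construction; reported
  synthetic performance upper-bounds nothing about clinical data.
- Fiducial detection assumes a dominant, regular QRS (no arrhythmia or
  paced rhythms) and fails loudly otherwise.
- The optimizer is plain gradient descent with a fixed step; it is chosen
  for determinism, not speed, and the epoch budget is a tunable, not a
  convergence guarantee.
- PPV/NPV intervals treat the counts as independent binomials at the
  observed prevalence, as the usual Table-2-style reporting does.
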