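# Methods

## Problem and model

The package classifies short windows of ankle acceleration into normal
gait (NG) versus freezing of gait (FoG), with three deliberate design
pressures: (i) FoG is rare, so class imbalance must be handled
explicitly; (ii) a cueing device must fire *before* the freeze when
possible, so the labeling and evaluation distinguish prediction
(pre-onset) from detection (post-onset); (iii) misses are costlier than
false alarms, so the decision rule is cost-sensitive.

The classification sample at time T stacks four features — freeze index,
sample entropy, total band power (0.5–8 Hz) and standard deviation —
from six successive 2 s windows (0.5 s stride, 4.5 s total lookback)
over four sensor-axis channels (left/right ankle x vertical/forward):
96 values. The sample is labeled FoG if the newest window contains at
least one FoG timestamp. Because the second before every true onset is
relabeled FoG during preprocessing, the two samples ending 0.5 s before
and at the onset are FoG-labeled, which is precisely what lets a
classifier fire pre-onset.

## Synthetic data: what it emulates, what it does not

No patient recordings ship with the package; the generator emulates the
*statistical structure* that the method depends on:

- **Normal gait**: stride-frequency sinusoid (default 1 Hz) plus one
  harmonic, left and right ankles half a cycle out of phase, forward
  axis at 0.7 x the vertical amplitude and a quarter-cycle offset.
- **FoG**: a single freeze-band tone (default 5 Hz) at
  `fog_amplitude` x the gait amplitude — the low-amplitude trembling
  seen during freezes.
- **Pre-onset transition**: the gait component's amplitude ramps
  linearly to zero over `pre_fog_transition` (default 1 s) before each
  freeze — gait arrest precedes trembling. This ramp is what makes the
  pre-onset windows statistically distinguishable from steady gait; with
  it removed, prediction (as opposed to detection) has no signal to
  learn.
- **Stops / no-activity**: noise-only segments.
- Everything is overlaid with white Gaussian noise (`noise_sd`).

Episode onsets follow a marked Poisson process. Defaults reproduce the
aggregate imbalance of a typical multi-patient laboratory protocol:
0.3 FoG episodes/min with durations uniform on (3, 11) s (7 s mean),
i.e. ~3.5 % of timestamps FoG; stop and no-activity rates (0.5/min and
0.1/min, durations 0.5–3 s and 1–5 s) are plausible values for an
instructed-stop walking protocol and are not calibrated to any dataset.

What the generator does **not** model: biomechanical gait variability
(stride-to-stride timing jitter, turning, festination), sensor
artefacts, drift and gravity leakage, patient heterogeneity, and any
correlation between freeze severity and signal amplitude. Tests passing
on this generator therefore demonstrate that the pipeline's machinery is
correct and that its direction-of-effect claims (cost and balance-level
monotonicity) hold on signals with the assumed band structure — not that
the reported accuracies transfer to clinical recordings.

## Numerical conventions

- **Resampling** 128 → 64 Hz is linear interpolation at the new sample
  instants; labels are categorical and take the nearest *preceding*
  original sample. Output length is floor(N·target/source).
- **Periodogram**: single rectangular (un-windowed) DFT of the de-meaned
  2 s segment; 0.5 Hz bin resolution exactly resolves the band edges.
  Power is scaled so an on-bin unit-amplitude sinusoid contributes 0.5
  signal-units². Band membership is by bin centre: locomotion [0.5, 3)
  Hz half-open, freeze [3, 8] Hz closed, so the two tile the total-power
  band [0.5, 8] exactly.
- **Freeze index cap**: when locomotion power is at machine-epsilon
  scale (silence, pure freeze tone) the ratio is undefined; a
  configurable cap (default 100) is returned, and the ratio is clipped
  at the same cap, keeping the feature bounded for downstream learners.
- **Sample entropy**: m = 2, r = 0.2 x window SD (the standard
  physiological-signal convention). Both template counts run over the
  first N − m templates so every length-m template has a continuation;
  self-matches are excluded. When A or B is zero the estimate is
  undefined and ln(#possible pairs) — a finite upper bound — is returned.
- **Standard deviation** is population (divide by N).
- **Window/label boundary**: a window's label is computed over the same
  sample-index range [w·S, w·S + L) its features use. An onset falling
  exactly on a window's end time lands in the *next* window, but the 1 s
  pre-FoG relabeling guarantees the window ending at the onset is still
  FoG-labeled; this convention yields exactly two pre-onset FoG samples
  per onset.
- **Exclusion thresholds** are strict (stop > 1 s, no-activity > 2 s).
  Only the newest window of a sample must be free of excluded data;
  older windows may overlap exclusions, since requiring purity over the
  whole 4.5 s history would discard most data around every stop.
- **Label-editing order**: pre-FoG relabeling runs before exclusion so
  it can skip stop/no-activity samples in the pre-window. The composed
  chain is a pure function of the original four-state track. Note that
  it is *not* idempotent under literal re-application — relabeling moves
  the apparent onset 1 s earlier, so feeding the edited track back
  through the rules would extend the relabeled span; the pipeline always
  edits the original track once.
- **Latency quantization**: predictions advance on the 0.5 s stride
  while true onsets fall anywhere, so the reported per-episode latency
  is the raw first-hit difference rounded to the nearest 0.5 s — the
  measurement resolution of the system. The search window spans 2 s
  before to 4 s after each onset (configurable), and a prediction inside
  two overlapping search windows counts toward the nearest onset.

## ADASYN

G = round((|S_maj| − |S_min|)·β) synthetic minority samples are
allocated across minority points by largest-remainder rounding of the
normalised majority-neighbour fractions r̂_i, so Σg_i = G exactly and
β = 1 balances the classes to within one sample. Neighbour searches use
Euclidean distance on per-dimension z-scored features (fit on the
training set), because the raw features differ in scale by orders of
magnitude (entropy vs power); synthetic coordinates are produced in the
original feature space as x_i + λ(x_z − x_i), λ ~ U(0, 1), x_z a random
minority neighbour. k = 5 by default. If no minority point has any
majority neighbour (fully separated classes) the allocation falls back
to uniform with a warning. Synthetic rows carry a flag and the
evaluation protocols refuse them in test sets.

## Cost-sensitive classification

Costs form a 2x2 matrix with zero diagonal; C_NG = 1 throughout and
C_FoG ∈ {1, 2, 3} by default. Multiplying each class prior by the cost
of missing that class and renormalising is equivalent to predicting FoG
when p(FoG | x) ≥ C_NG/(C_NG + C_FoG). Implementing cost as this
posterior-threshold shift (rather than per-learner native options) keeps
the semantics identical across learner kinds and makes sensitivity
provably non-decreasing — and specificity non-increasing — in C_FoG for
any fixed fitted model.

Base learners (hyperparameters exposed in `BaseLearnerSpec`):

- SVM: RBF kernel, probability-calibrated scores (Platt scaling);
- kNN: k = 5, distance-weighted votes;
- MLP: one hidden layer of 32 units, Adam, loss-plateau stopping
  (tol-based, `n_iter_no_change` = 20, `max_iter` = 400). Validation-set
  early stopping was tried and rejected: on small training sets the
  validation accuracy plateaus at its ceiling while the decision
  function is still uncalibrated, so training halts prematurely.

All learners sit behind a pipeline that drops constant feature columns
(with a warning) and z-scores the remainder, fit on training data only.

**ClsfBagging** fits each member (default one SVM, one kNN, one MLP) on
an independent bootstrap resample and takes a hard majority vote of the
members' cost-thresholded decisions; ties break toward FoG when
C_FoG > C_NG. Soft (average-probability) voting is available behind a
flag. **ClsfBoost** cycles through the member kinds with AdaBoost-style
reweighting; because kNN and MLP accept no per-sample weights, each
round fits on a weighted resample, and a round with weighted error
≥ 0.5 stops boosting, keeping earlier rounds. The tree ensembles
delegate to the standard algorithms, with TreeBagger = bagged trees
using all features per split and RandomForest using sqrt-features.

## Evaluation protocols

Patient-dependent: chronological per-subject 60/40 split (the
chronological ordering prevents the 75 %-overlapping windows from
leaking across the split); one model per subject; metrics averaged
unweighted across subjects. Patient-independent: leave-one-subject-out,
with ADASYN applied to the pooled training folds only; folds whose
held-out subject has no FoG get an undefined sensitivity and are
excluded from the sensitivity average with a note. Metrics with zero
denominators are reported as undefined (`None`), never as numbers.
Episode identification is counted at the episode level (an episode is
identified if any FoG-classified sample falls in its −2 s…+4 s search
window); a sample-level variant is not provided.

## Problem sizes in the test suite

The heavier gates run on pooled sets of twenty 45 s recordings per seed
(10 seeds) for the monotonicity checks, and eight 60 s recordings for
the end-to-end recovery check, with the FoG episode rate raised to
2/min so that short recordings reliably contain episodes; the
generator's clinical-imbalance defaults are unchanged. The monotonicity
check trains ClsfBagging once per (seed, β) and sweeps C_FoG as a pure
prediction threshold on the fitted model, which is exact for bagging
because cost never enters member training.

## Known limitations

- The signal model is deterministic narrow-band; real FoG trembling is
  broadband and non-stationary, and real pre-FoG signatures are far
  subtler than a clean amplitude ramp.
- ClsfBoost's weighted-resampling approximation to weighted fitting adds
  Monte-Carlo variance that true weight-aware learners would not have.
- The latency profile assigns at most one latency per episode (first
  hit); duration of the detected span is not scored.
- Sample entropy is O(N²) in window length; fine at N = 128, not meant
  for long windows.
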