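# Methods

## Signal representation

A TeUS recording summarizes each ROI as a time series of mean echo
intensities, one per RF frame.  When starting from raw RF-frame stacks,
`preprocess.average_rf_grid` tiles the frame with non-overlapping grid
cells (default 44 axial samples × 2 lateral lines = 88 RF values,
a 1.7 × 1.7 mm window) and averages each cell per frame; partial
trailing cells are dropped because frame extents rarely divide evenly
and edge cells would mix tissue with out-of-grid content.

Modeling operates on the first-order difference series — the pattern of
echo-intensity *change* carries the tissue information, and differencing
removes the static intensity offset (including any patient-level gain).
The differences are quantized into `M` equal-width bins fitted to the
pooled training deltas of **both** classes.  Sharing one quantizer per
training fold is essential: the two HMMs must emit over a common
alphabet for their log-likelihoods to be comparable.  Bins are half-open
with a closed top bin; test-time values outside the fitted range clamp
to the extreme bins rather than raising, since held-out patients may
exceed the training range.  A degenerate fitted range (all deltas equal)
widens to ±0.5 around the common value.

## The HMM pair

Both models are discrete ergodic HMMs with the start distribution pinned
to state 1 (`π = (1, 0, …, 0)`), held fixed throughout training — the
generating process is assumed to start in a designated state, and
re-estimating `π` would contradict that assumption while adding `N − 1`
parameters.

**Initialization.**  The observed symbol values of the training
sequences are clustered by 1-D K-means with `K = N`, initialized at the
`K` evenly spaced quantiles of the data.  This is deterministic by
construction (no random restarts): reproducibility across runs and
machines was valued over marginal fit quality, and on 1-D data quantile
initialization is close to optimal anyway.  Ties in assignment break
toward the lower-index cluster; clusters are relabeled by ascending
centroid so state 1 is always the "most negative change" state.
Emission row `i` is the floor-smoothed empirical symbol distribution of
cluster `i`; transition row `i` counts consecutive-position cluster
moves pooled over sequences.

**Training.**  Multi-sequence Baum–Welch EM treats the training
sequences as independent, maximizing the product of per-sequence
likelihoods.  Forward–backward passes use the classical per-step scaling
recursion (not log-space matrix arithmetic), which is exact in the log
domain and stable far beyond the 127-step sequences used here.
Sequences of equal length are processed as vectorized batches.

Numerical choices:

- `prob_floor` (default 1e−6): after every M-step, transition and
  emission entries below the floor are raised to it and rows
  renormalized.  Without a floor, a single test symbol unseen in
  training would give likelihood −∞ and break the argmax decision.
- Convergence: relative log-likelihood change below `tol = 1e−6`, or
  `max_iter = 200` iterations (the recovery experiment in
  `scripts/acceptance.py` raises the cap to 500 to run to full
  convergence).  The per-iteration log-likelihood trace is recorded and
  checked to be non-decreasing within 1e−8 absolute slack.
- All-zero expected-count rows (a state never visited) re-estimate to
  uniform rather than propagating NaNs.

## Classification

`log_odds = log Pr(O|λ_B) − log Pr(O|λ_M)`; the label is benign iff
`log_odds > 0`, which is exactly the two-model argmax rule.  Exact ties
resolve to **malignant** — the clinically conservative choice, since a
false negative (missed cancer) is costlier than a false positive.  The
quantizer travels inside the trained `ModelPair`, so test-time
preprocessing always matches the training fold's.

## Evaluation

Folds are whole patients (leave-one-patient-out), because ROIs from one
patient are spatially and physiologically correlated; fold order is the
sorted patient ids.  Per-fold training sees nothing of the held-out
patient — including the quantizer fit, which is re-run per fold.

Metrics per patient: accuracy, sensitivity (malignant recall),
specificity (benign recall).  For ROC analysis the log-odds of a
held-out patient's ROIs are normalized by
`s(x) = 0.5 + x / (2·max|x|)` (an all-zero vector maps to 0.5), so 0.5
always corresponds to the zero-log-odds decision boundary; the
malignancy score is the normalized negated log-odds, and AUC is the
trapezoidal area, which on the full threshold sweep equals the pairwise
rank statistic.  Patients without malignant ROIs have undefined
sensitivity and AUC; these are reported as *missing*, never as zero, and
the cohort "average" row averages sensitivity/AUC only over patients
that have malignant ROIs while averaging the other measures over all
patients.  The pooled ROC (`pooled_roc`) instead normalizes all
patients' log-odds jointly.

The grid search sweeps `N ∈ {2..8}` × `M ∈ {10, 20, 30, 40, 50}` (35
cells), reporting per-cell mean and sample standard deviation of the
per-patient accuracies (spread across patients, not across reruns).
Fold seeds derive deterministically from `(base seed, N, M, fold
index)`, so cells are independent of evaluation order.

Accuracy vectors of competing configurations can be compared with the
one-tailed Mann–Whitney–Wilcoxon test (`rank_sum_test`): midranks for
ties; the p-value comes from exact enumeration of the rank-sum null
distribution (a generating-function dynamic program over all
`C(n+m, n)` equally likely rank assignments) when `n·m ≤ 400`, else from
the normal approximation with tie and continuity corrections.  The exact
branch is implemented in-package because standard exact routines do not
handle midrank ties.

## Synthetic cohorts

The generator emulates what TeUS plausibly looks like at the ROI level:

```
x_t = baseline · g_p + Σ_{k=1,2} a_{c,k} · sin(2π f_k t / 77 + φ_k) + σ ε_t
```

with per-ROI frequencies `f_k` uniform in the 1–2 Hz micro-vibration
band, uniform phases, Gaussian noise `σ = 0.05` (intensity units), and a
lognormal per-patient gain `g_p` (σ = 0.15) multiplying the baseline
(100).  The classes differ only in the amplitude pair `a_c`:
malignant (2.0, 1.0) vs benign (0.8, 0.4).  These effect sizes are a
free design choice — no quantitative class-conditional TeUS spectra are
available to copy — set once so that the default classes are separable
with a clear margin yet not trivially (the random frequencies make the
per-step delta scales of the two classes overlap; default LOPO accuracy
is ≈ 0.95, not 1.0).  Default cohort size is 12 patients × 12 ROIs per
class, a desk-scale stand-in for a clinical cohort's hundreds of ROIs.

Randomness is counter-based: ROI `(p, j)` draws from the substream keyed
by `(p, j)` regardless of class, and the per-patient gain from `(p,)`.
Consequences: adding patients or ROIs never perturbs earlier data, and
the class label influences only the amplitude parameters — swapping the
class amplitude pairs exactly swaps the malignant and benign series.
The last `benign_only_patients` patients receive no malignant ROIs,
emulating patients whose pathology showed no clinically significant
malignancy.

`generate_null_cohort` is the calibration control: both classes use the
benign amplitudes, drawn from two independent seed substreams, so labels
carry no signal and LOPO accuracy should sit at chance.

**What the generator does not emulate:** speckle statistics, acoustic
propagation, depth-dependent time-gain compensation, spatial correlation
between neighboring ROIs, registration/labeling error, or class
imbalance at the paper-data scale.  Passing tests therefore demonstrate
that the pipeline recovers class-dependent temporal dynamics under the
stated signal model — not clinical performance on in vivo data.

## Fixture models

`make_toy_pair` hard-codes two well-separated 3-state/10-symbol HMMs
(stationary emission mixtures differ by total variation ≈ 0.64) used
throughout the tests for sampling, likelihood discrimination and
parameter-recovery experiments.  Recovery is judged on emission rows
after the best state permutation, since HMM states are identifiable only
up to relabeling.

## Problem sizes

The test suite and acceptance script run at desk scale by design:
12-patient × 12-ROI cohorts for the end-to-end study (≈ 240 sequences of
length 127), 800 sequences for parameter recovery, a 6-patient null
cohort, and a reduced-iteration grid search for protocol-shape checks.
These sizes were chosen as the smallest at which the statistical checks
are comfortably stable.

## Known limitations

- Equal-width bins are sensitive to single extreme deltas (they stretch
  the range); the clamping rule bounds the damage at test time but a
  heavy-tailed training ROI still coarsens the central bins.
- Deterministic K-means initialization can land EM in a local optimum; a
  restart strategy would trade reproducibility for fit quality.
- Per-patient ROC normalization makes AUCs comparable across patients
  but not across cohorts with very different log-odds scales.
- The CLI's cohort CSV carries no frame-rate column; non-default frame
  rates must be supplied programmatically.
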