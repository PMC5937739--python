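# Methods

## Scope

`hybridbci` implements offline decoding of mental arithmetic (MA) vs.
relaxed baseline (BL) from simultaneously recorded frontal EEG and
prefrontal NIRS, plus a generative model of such sessions. This note
records the models, the defaults and why, what the synthetic generator
does and does not emulate, and the numerical choices.

## Generative model (`synthgen`)

A session is pre-rest (15 s) → 20 trials (instruction 2 s, task 10 s,
rest uniform 15–17 s) → post-rest (15 s); the default recording is
3 sessions = 60 trials, chosen so 5-fold cross-validation keeps ≥ 12 test
trials per fold (the number of sessions per participant is not fixed by
the paradigm and is configurable). Labels are drawn balanced within each
session (|#MA − #BL| ≤ 1). Trial onsets are snapped to the 0.08 s NIRS
sample grid, which is a common multiple of the 1000 Hz and 200 Hz EEG
grids, so every epoch has the same sample count.

**EEG (µV, 1000 Hz, 22 scalp + 4 EOG channels).** Each scalp channel is
1/f Gaussian noise (10 µV RMS) plus one α source (narrowband noise at
10 ± 1 Hz, 20 µV) with a fixed posterior-dominant topography (frontal
weight 0.55) — α is present everywhere with closed eyes. The α amplitude
is gated: weak (×0.35) with eyes open, full during the eyes-closed
instruction+task span, and attenuated by `alpha_attenuation_ma` (default
0.45) during MA tasks. Ocular sources are < 4 Hz drifting-gaze noise plus
blink pulses on the vertical channels, mixed with frontally dominant gains
(0.18 frontal → 0.015 occipital).

**NIRS (9 channels, 12.5 Hz).** Neural drive is a per-trial boxcar over
the task, convolved with a double-gamma impulse response (unit-rate gamma
densities with modes at `hrf_peak_s` = 6 s and `hrf_undershoot_s` = 16 s,
undershoot ratio 1/6), normalised so one 10 s task peaks at 1; with these
defaults the response peaks 10–15 s after task onset, which is why the
late window carries the discriminative information. Peak concentration
amplitudes are (HbO, HbR) = (0.6, 0.2) µM for MA and (0.3, 0.1) µM for BL
(MA activates more strongly), HbR with negative sign. Nuisance terms:
random-walk drift (0.2 µM), cardiac/respiratory/Mayer sinusoids at
1.0/0.3/0.1 Hz (0.08 µM), white concentration noise (0.04 µM). The clean
concentrations go through the forward Beer–Lambert model
I = I₀·10^(−ε·d·DPF·Δc) to produce strictly positive raw intensities, and
are kept as ground truth.

**Single-trial variability.** Both effects carry lognormal per-trial
amplitude factors (σ = 0.4 for α, σ = 0.4 for the HRF). These are the
decisive realism parameters: without them every decoder saturates at
100 %. With them, the defaults were calibrated once so that the default
world reproduces the published group operating point (unimodal accuracies
in the mid-70s, hybrid in the 80s); they were then frozen. A rough
back-of-envelope: the MA/BL log-band-power separation is
2·ln(1/(1−0.45)) ≈ 1.2 against a per-trial log-power σ of ≈ 2·0.4, i.e.
d′ ≈ 1.5 ≈ 77 % accuracy.

**Not emulated:** volume conduction/head geometry, pupil or eyelid
dynamics, photon transport (the Beer–Lambert forward model is the exact
inverse of the analysis step, so the optics contribute no model error),
non-stationary artifacts (motion, electrode drift), inter-participant
variability of spectra or HRF shape. A green pipeline test therefore
establishes internal consistency and statistical correctness of the
decoder, not robustness to real-world artifacts.

## Preprocessing (`preproc`)

Order: EEG decimate → band-pass → ocular rejection; NIRS Beer–Lambert →
band-pass. All filters are Butterworth, applied forward–backward
(zero-phase; effective order doubles — accepted for offline analysis so
that epoch timing is phase-true).

* Decimation 1000 → 200 Hz with an 8th-order Butterworth low-pass at
  0.8 × the new Nyquist (80 Hz). A maximally flat design is used so a
  constant signal survives exactly (an equiripple design would impose its
  passband ripple on DC).
* EEG band-pass 0.5–50 Hz, order 3; NIRS band-pass 0.01–0.2 Hz, order 6.
  The 0.01 Hz high-pass is the only drift handling — no per-epoch baseline
  subtraction.
* Ocular rejection: SOBI-style blind source separation on the stacked
  EEG+EOG block — whiten (with rank truncation at 1e-10 of the largest
  eigenvalue, which makes the zero-EOG case an exact identity), jointly
  diagonalise symmetrised lagged covariances (lags 1…120 samples,
  Cardoso–Souloumiac Jacobi sweeps), zero every source whose absolute
  correlation with any EOG channel exceeds 0.7, back-project. Deterministic
  and seed-free. A least-squares regression fallback
  (`method="regression"`) is provided.
* Beer–Lambert: ΔOD = −log₁₀(I/I₀) with I₀ the per-channel mean over the
  whole recording (a baseline window is configurable);
  [ΔHbO, ΔHbR]ᵀ = (ε·d·DPF)⁻¹ ΔOD per sample. Defaults: Gratzer/Cope
  extinction at 760/850 nm in 1/(mM·mm), DPF 5.98/5.07, d = 30 mm.
  Units: concentrations mM, distances mm.
* Epoching uses half-open [start, end) windows relative to task onset,
  0-based sample indexing, sample k at time k/rate; at 12.5 Hz the
  [10, 15) s window holds 63 samples when the onset lies on the grid.

## Features (`features`)

* sgn r² = sign(r)·r² with r the point-biserial correlation against
  MA = 1 / BL = 0; positive means larger in MA.
* Band selection: Welch spectra (1 s Hann segments, 50 % overlap,
  zero-padded to a 0.5 Hz grid), per-bin log band power averaged over
  channels, scored by sgn r² on training trials only. The band seeds at
  the extremal-score bin and grows toward the better neighbour while that
  neighbour contributes ≥ 5 % of the running score sum with the same sign.
  Search range 4–35 Hz; exactly zero discriminability falls back to the
  full range. The stopping fraction is a convention (the cited heuristic's
  exact tolerances are not published); 0.05 gives bands of a few Hz around
  α on the synthetic data, matching the published per-participant bands.
* CSP: per-trial covariances divided by their trace, class-averaged;
  generalised eigenproblem Σ₁w = λ(Σ₁+Σ₂)w via `scipy.linalg.eigh`, with
  a 1e-10·tr/n ridge on the composite for rank safety. λ sorted
  descending, clipped to [0, 1]. Component selection is by the
  ratio-of-medians score (3 per extreme, fewer symmetric if < 6 channels);
  ties resolve to the earlier (λ-ordered) component.
* Log-variance features are normalised by the per-trial sum over selected
  components (standard practice; the unnormalised variant is available).
  An all-zero projected trial raises; an isolated zero-variance component
  is floored at 1e-300 with a warning.
* NIRS features: window mean and least-squares slope per channel (slope
  rather than endpoint difference: robust to band-pass phase at the window
  edges).

## Decoding (`decode`)

* Shrinkage LDA: pooled class-centred covariance Σ̂ (biased, n in the
  denominator), target νI with ν = tr(Σ̂)/d, analytic Ledoit–Wolf
  intensity clipped to [0, 1] (verified against scikit-learn's
  `LedoitWolf`). w = Σ̃⁻¹(m₁−m₂), bias at the class-mean midpoint (equal
  priors — the paradigm is balanced). γ = 0 is allowed only when d ≤ n.
* Fusion: the meta-feature is the vector of continuous base scores
  (confidence is preserved; hard labels would discard it), classified by a
  second sLDA. Meta-training scores are generated out-of-fold by an inner
  stratified 4-fold split of each outer training fold, so the meta level
  never sees resubstitution scores. Within the inner folds the CSP (and
  sLDAs) are re-fit; the passband is re-used from the outer training fold
  — its selection is the costly step and its leakage surface (toward the
  outer test set) is unchanged.
* Nested CV: 10 repetitions × stratified 5 folds (per-fold class imbalance
  ≤ 1); band selection, CSP, base and meta classifiers are all re-fit per
  outer fold, and every fitted object stores a hash of its training
  indices as a leakage audit. One master seed spawns per-repetition
  streams; identical seeds give identical results. Per-trial Welch spectra
  and band-filtered epochs are cached across folds (both are
  fold-independent quantities), which makes the full protocol run in
  seconds.
* Accuracy is the percentage of correct test trials per fold, averaged
  over the 50 folds. "NIRS" denotes the HbR+HbO fusion and "HYB" the
  EEG+HbR+HbO fusion.

## Evaluation (`metrics`)

* ITR (bits/min) with m = 6 trials/min (10 s task, rest excluded) and
  N = 2; P = 1 uses 0·log 0 = 0. For N = 2 the bit term is symmetric about
  chance and never negative. Group ITR is the mean of per-participant
  ITRs — ITR is convex in P, so this exceeds the ITR of the mean accuracy
  (Jensen), and it is the convention the published averages follow.
* Friedman with average-rank ties (scipy), Wilcoxon signed-rank exact for
  ≤ 25 non-zero differences (normal approximation with continuity
  correction above; zeros dropped), Benjamini–Hochberg step-up FDR
  (statsmodels). Group stds of the published table are computed but not
  asserted anywhere: the printed std was evidently computed on unrounded
  accuracies and cannot be recovered from the rounded column.
* The window sweep re-runs the full nested CV per (EEG window, NIRS
  window) pair, one axis varied at a time.

## Known limitations

* The published per-participant accuracies cannot be reproduced without
  the original recordings; only summaries derived from the printed table
  are asserted.
* The importers (EDF, BrainVision, SNIRF) are minimal read-only mappers
  onto the frontal montage, not general-purpose readers.
* The BSS separation assumes stationary mixing over the recording and
  temporally structured (coloured) sources; heavily rank-deficient or
  very short recordings fall back poorly and the regression method should
  be preferred there.
* Whether the original analysis epoched before or after ocular rejection,
  and whether I₀ was session-wide or pre-trial, is not documented;
  continuous cleaning and session-wide I₀ are used.
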