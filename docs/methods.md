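# Methods

## The task and its measures

The paradigm is a continuous visuo-haptic tracking task.  A dot moves at
20°/s around an annulus whose width — the target force — varies nonlinearly
over each 60° cycle, so one cycle spans exactly 3 s and the target-force
pattern in the 3 s before every thought probe is identical across trials.
The dot's diameter maps linearly from the exerted force, `D = k·F + D₀`
with k = 3 mm/N and D₀ = 0.5 mm, over an allowable range of 0.5–3.17 N
(diameters ≈ 2.0–10.0 mm).  Thought probes appear every 40–50 s; the rating
(0 = fully on task, 100 = fully distracted) labels the preceding 3-s window.

Tracking performance is the normalized squared error
`BE_NL = Σ(F_target − F_output)² / ΣF_target²`, computed in 1-s windows with
90% overlap (21 windows per trial) and summed into `BE_NL-trial`.  The
formula is implemented exactly as written — no square root — so `BE_NL` is 0
for perfect tracking and 1 for zero output.

Per participant, trials in the lowest rating quartile become onT and the
highest quartile MW: floor(n/4) trials each, ties broken by rating rank and
then trial index, so the classes are always exactly balanced and the
decoding chance level is exactly 50%.

## The synthetic-data generator

No public recording accompanies this analysis, so the generator is the
test bed: it emulates the statistical structure the analysis is designed to
detect, with every output a pure function of (configuration, seed).

* **Target force** — a raised cosine taken to the power 2 spanning
  [0.5, 3.17] N over the 3-s cycle.  Any smooth nonlinear periodic profile
  in range would do; this one is demonstrably non-affine (the tests fit a
  line by the normal equations and check nonzero residual).
* **Ratings** — linear drift (default 1.2 points/trial) plus Gaussian noise
  (SD 12), clipped to [0, 100], from a per-participant baseline of 15–35.
  Over 36 trials this produces the observed upward drift of off-task
  reports while leaving quartile structure intact.
* **Output force** — target plus Gaussian noise smoothed to tracking-like
  bandwidth (Gaussian kernel, σ = 50 ms), SD 0.15 N on a fully on-task
  trial rising by 80% on a fully mind-wandering one, clipped to the
  allowable range.  The noise level follows the trial's rating rank with
  weight 0.7 (the rest is trial-specific), which yields positive
  rating–error correlation and `BE_NL-trial` means of ≈0.19 (onT) vs.
  ≈0.39 (MW) — the right order of magnitude for this task.
* **EEG epochs** — 1/f background (exponent 1, 5 µV RMS) plus per-channel
  theta (4.5–5.8 Hz, ~3 µV) and alpha (8.7–10 Hz, ~4 µV) oscillators with
  epoch-random frequencies and phases.  Condition effects enter as linear
  functions of a blend level: 0 for bottom-quartile trials, 1 for
  top-quartile, ramping linearly between, so labels and injected effects
  agree by construction.  The five effects:
  1. alpha amplitude ×1.5 at the frontal and posterior effect electrodes
     in MW;
  2. at PO3/PO4 the alpha peak is drawn at 2.8× the theta peak with
     probability 0.65 (onT) vs. 0.35 (MW) — the harmonic-ratio effect;
  3. a shared alpha-band source (8.8–9.6 Hz) mixed into LC (weight 1.2),
     F/RC (0.6) and PO (0.45) with coupling 0.45 in MW — this raises PLV
     within LC and across F–LC, LC–RC and RC–PO;
  4. the alpha envelope at F1–F6 (carrier 7.8–8.6 Hz) is modulated by the
     trial's windowed BE_NL series with depth 0.6 (onT) vs. 0.15 (MW) —
     the neural–behavioral coupling effect;
  5. the force-noise effect above.
  The random-draw layout is identical at every level, so with a neutral
  effect configuration onT and MW epochs are bit-identical at the same
  seed — exchangeability under the null holds exactly, which the
  permutation-test calibration checks exploit.

What the generator does **not** emulate: artifacts (blinks, EMG, line
noise), volume conduction and field spread, inter-individual anatomy,
nonstationarity within an epoch, or realistic connectivity baselines.
Passing tests therefore demonstrate that the pipeline recovers the intended
statistical structure when it is present and stays calibrated when it is
absent — not that real recordings would classify at the accuracies printed
here.  On this clean, strongly structured data the combined-feature LOSO
accuracy approaches 100%; on human data the same pipeline would face far
lower effect-to-noise ratios.

## Feature extraction

* **Spectral power.** Per trial and electrode, 1-s Hann windows with 90%
  overlap (21 windows), zero-padded to a 0.1 Hz grid over 2–45 Hz (431
  points), one-sided periodogram scaling, averaged over windows, natural
  log.  The zero-padding interpolates a 1 Hz native resolution onto the
  fine grid; absolute power scale cancels in all condition contrasts, and
  the log base only rescales them.
* **Alpha:theta ratio densities.** The time-varying spectrum is sampled
  every 100 ms (30 time points per epoch).  Each time point's spectrum
  comes from a 1-s Hann-tapered segment centred on it (zero-padded at the
  epoch edges), zero-padded in frequency to 0.1 Hz over 4–13 Hz.  The 1-s
  spectral support is essential: a raw 100-ms frame has 10 Hz resolution
  and cannot separate theta from alpha peaks at all (measured hit rates
  ~37%/57%), whereas with 1-s support the per-time-point peak detection
  hits in 93–99% of frames — the regime the method's reported detection
  rates describe.  Per band the peak is the highest-amplitude strict local
  maximum (plateaus collapse to their lowest frequency; band endpoints
  never qualify).  Ratios are binned into 23 half-open bins of width 0.1
  with left edges 1.1–3.3; proportions are relative to time points with
  both peaks detected (the valid-frame fraction is recorded; an all-frames
  denominator is available).  Note that window sidelobes of a strong alpha
  rhythm can register as weak theta-band maxima; with no amplitude
  threshold specified for the detector, such frames contribute low ratios.
* **PLV.** Zero-phase Butterworth band-pass (order 4, default 8–10 Hz, the
  band carrying the power contrast), analytic-signal phase, 250 ms guard
  discarded at each epoch end, `PLV(i,j) = |⟨exp(i(φᵢ−φⱼ))⟩ₜ|` per epoch,
  then averaged per condition.  Community connectivity averages PLV over
  intra-community pairs (diagonal excluded) or all cross pairs for the
  communities F (Fp/AF/F/FT/FC rows, 26 electrodes), LC (left C/CP rows,
  8), RC (right C/CP rows, 8), PO (P/PO/O rows, 20); Cz and CPz stay
  unassigned.
* **Mutual information.** X is the 21-point windowed BE_NL series, Y the
  21-point log-power time course at one (electrode, frequency) from the
  identical window scheme.  The plug-in estimate uses a 4×4 equal-width
  histogram (≈√n rule at n = 21), in bits, clipped at 0; rank (copula)
  binning is available and makes the estimate exactly invariant under
  monotone transforms.  At n = 21 the estimator bias
  ≈ (b−1)²/(2n ln 2) ≈ 0.3 bits is substantial but identical across
  conditions, so it cancels in every contrast.

## Statistics

Condition contrasts are within-participant, so the permutation scheme is a
per-participant condition swap — a sign flip of each participant's
condition difference.  Cluster tests threshold the pointwise paired t-map
at the two-sided p < 0.05 critical value, cluster same-sign supra-threshold
points under montage adjacency (Delaunay triangulation of the projected
positions with overlong edges dropped) plus feature-axis contiguity, score
clusters by summed t, and compare each against the permutation null of the
maximal same-sign cluster mass (1000 permutations by default; add-one
p-values, so the smallest attainable p is 1/(n_perm+1)).  Positive and
negative clusters are tested against their own sign's null; the per-tail
significance threshold (0.025 for a 0.05 family level) is the caller's
parameter.  Measured type-I rate on exchangeable data: 5.5% at the nominal
5% over 500 replicates.  The network-based edge test applies the same
machinery to PLV matrices: edgewise paired t, edges past a (configurable,
deliberately strict) edge threshold, components connected through shared
electrodes, scored by edge count (or summed |t|).  The two-level
repeated-measures ANOVA uses the exact identity F = t² with df (1, n−1);
the observation unit (participants, or trial pairs when mimicking
trial-level dfs) is the caller's choice.

Degenerate inputs are flagged, not silently dropped: zero-variance paired
differences give a sign-carried infinite t with p = 0, constant series give
MI 0, empty ratio series give an all-zero density vector.

## Decoding

The default feature layout is fixed and label-independent: mean 8–10 Hz log
power over the frontal and over the posterior effect electrode groups (2
features), mean 2.6–3.0 ratio density at PO3/PO4 (1), the LC, F–LC, LC–RC
and RC–PO community PLVs (4), and mean 7.2–8.8 Hz MI at F1–F6 (1).  Because
this layout never sees the labels, it cannot leak test information into
training.  A data-driven alternative (`clusterwise_feature_blocks`) selects
significant-cluster points from any participant subset — run it on each
LOSO fold's training participants for leakage-free selection, or on all
data to mimic a select-then-validate protocol; the latter can only score
higher and is reported as an upper bound, not as correctness.

Standardization uses the training fold's mean and population SD (divide by
n — the convention under which a two-point column (1, 3) maps to (−1, 1));
zero-SD columns are dropped with a notice.  The SVM uses an RBF kernel with
C = 1 and γ = 1/n_features, no hyperparameter search.  LOSO aggregates
metrics over participant folds; 5-fold CV stratifies within participant
(shuffled with a logged seed, k reduced with a warning when trials are
scarce) and aggregates over participant-fold pairs, mean ± SD.  AUC uses
decision-function scores, MW positive.  Chance level was verified
empirically: mean LOSO accuracy over 100 within-participant label
permutations of the default dataset is ≈49.6%.

## Problem sizes and numerical choices

The default study conditions are 9 participants × 36 trials (3-s epochs,
64 channels, 1 kHz) — the acceptance script and the heavy tests run at
exactly these sizes; unit tests use smaller synthetic fragments.
Permutation counts are 1000 by default and 100–200 in calibration
simulations, where the binomial width of the check, not the p-value
resolution, dominates.  FFTs run in single precision on float32 epochs;
all tolerances in the tests reflect estimator variance (Monte-Carlo
spread, correlated zero-padded bins, filter transients) rather than
implementation slack.

## Known limitations

Sensor-space PLV is uncorrected for volume conduction (no imaginary
coherence/wPLI variants); the MI estimator is the plain plug-in histogram
(no k-NN or bias-corrected estimators); EEG preprocessing (filtering,
re-referencing, artifact rejection) is out of scope — the generator emits
clean signals; EDF export is not provided (no EDF writer among the
package's dependencies), dataset persistence is HDF5 + CSV + JSON with
exact round trip.
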