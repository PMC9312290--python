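# Methods

This note documents the models implemented in `ecgfusion`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions used throughout.

## Problem setting

Each record is a 12-lead ECG (sampling rate 500 Hz, 6–60 s) carrying a
*set* of rhythm labels from {Normal, AF, PVC, PAC, LBBB, RBBB}; label
sets of size 2–3 are common in clinical corpora, so all modeling and
evaluation is multi-label. The pipeline is: fiducial detection →
118-attribute feature extraction → sparse multi-label attribute
selection → sliding-window matrix construction → CNN-GRU classification
→ multi-label metrics.

## Synthetic generator

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with fixed
offsets/amplitudes/widths (e.g. R: 1.0 mV, σ = 11 ms at the beat time;
P: 0.15 mV at −160 ms), projected to 12 leads through a fixed amplitude
table with lead II as the reference. Beats repeat at RR intervals
`60/HR · (1 + jitter·ε)`, ε ∼ N(0,1) truncated at ±3, RR floored at
0.3 s. Class effects:

| class | morphology | rhythm |
|---|---|---|
| Normal | template as-is | RR jitter CV 0.03 |
| AF | P amplitude ×0 | RR jitter CV 0.18 |
| PVC | ectopic beats (p = 0.25): QRS width ×2.2, R ×1.3, no P | background normal |
| PAC | ectopic beats (p = 0.25): early arrival (RR ×0.7), altered P | background normal |
| LBBB | every beat: QRS width ×1.9, inverted T, V1–V3 QRS polarity flipped | normal |
| RBBB | every beat: QRS width ×1.7, V1/V2/V6 QRS polarity flipped | normal |

Records with several labels interleave beats in alternating blocks of
four, so each beat's morphology is attributable to one class. A record
labeled with an ectopic class is guaranteed at least one marked beat.
Noise is additive white Gaussian only (default SD 0.02 mV).
Dataset-level label sets are independent Bernoulli draws per class with
prevalences defaulting to a clinical corpus' per-class record
frequencies (Normal 0.18, AF 0.24, PVC 0.14, PAC 0.12, LBBB 0.05, RBBB
0.36); empty sets are redrawn, which scales the expected frequencies by
1/(1 − P(all classes absent)).

**What this does not emulate:** baseline wander, powerline interference,
electrode artifacts, dynamical beat-to-beat coupling (no ODE heart
model), realistic P/T axis variation, and inter-patient variability
beyond heart rate and jitter. Passing tests on this data demonstrates
the pipeline's mechanics (detection, extraction, selection, learning,
scoring), not clinical performance; metrics here are far above what any
method achieves on real clinical corpora.

## Fiducial detection

R peaks: band-pass 5–15 Hz (order-2 Butterworth, zero-phase) →
derivative → squaring → 150 ms moving-window integration → adaptive
signal/noise thresholding (threshold = noise + 0.25·(signal − noise),
running EMA updates with factor 0.125) → refinement to the local
maximum of the band-passed signal (±75 ms) → 200 ms refractory rule.
All thresholds are relative, making detection invariant to amplitude
scaling. This is a standard detector chain standing in for the published
external delineator used on clinical data; only its contract (strictly
increasing indices, refractory period) is relied on downstream.

Delineation windows (overridable): Q = minimum within 50 ms before R;
S = minimum within 50 ms after R; P = maximum in [−200, −80] ms;
T = maximum in [80, 400] ms truncated at the next beat, flagged absent
when the remaining window is shorter than 40 ms. Waves violating the
P < Q < R < S < T ordering are flagged absent. These are conventional
physiologic bounds; they cap measurable QRS width at ~100 ms, which
still separates wide-QRS classes from normal ones.

## Feature catalog

118 attributes in four families (27/35/30/26), addressed by name and
versioned (`catalog.CATALOG_VERSION`). The handful of attributes the
source taxonomy names explicitly (RR min/max, median heart rate, RMSSD,
spectral centroid, normalized low/high-band powers, wavelet sub-band
energies, Q/R/S depth, ST slope, QRS width, sample/approximate/fuzzy
entropy) anchor the families; the remainder are standard
HRV/spectral/morphological/complexity measures filling each family to
its fixed count. Units are recorded per attribute in the JSON manifest.

Numerical conventions:

* **Spectral** statistics use a Welch periodogram with ~1 Hz resolution;
  bands are 0–0.5, 0.5–5, 5–15, 15–40, 40–100, 100–Nyquist Hz (the
  lowest band includes DC so normalized powers sum to 1); the all-zero
  window has all band powers 0 and shape statistics NaN. Wavelet
  energies use a db4 decomposition at 5 levels (or as many as fit).
* **Entropies** (sample/approximate/fuzzy) use Chebyshev distance with
  d ≤ r matching, the grid (m, r/SD) ∈ {(2, .15), (2, .20), (2, .25),
  (3, .20)}, computed on the signal decimated to ~100 Hz — template
  counting is O(N²), and at 500 Hz it would dominate the pipeline's
  runtime without changing the complexity ordering the features encode.
* **Morphology** aggregates 15 per-beat quantities as mean and SD over
  beats with complete Q/R/S.
* **Sentinel policy:** any attribute undefined on a given input is NaN
  at extraction time and is imputed with the *training-set* column
  median before modeling; no NaN reaches the linear algebra. Short
  windows legitimately leave RR-based attributes undefined (a 2 s window
  holds 2–3 beats), so window-level time-domain columns carry little
  information at the default window size — the discriminative signal at
  window level comes mostly from spectral and morphological columns.

The sliding-window matrix (default 2 s windows, 1 s stride) has one row
per window: column 0 is the window RMS amplitude, the remaining columns
the selected attributes recomputed on that window, all z-scored with
parameters fit on pooled training windows (numerically constant columns
z-score to zero rather than dividing by ~0).

## Attribute selection

Objective (features d = 118, labels m = 6, instances n):

    min_W ||XW − Y||²_F + α·tr(F L₁ Fᵀ) + β·tr(Fᵀ L₂ F)
          + γ₁·||W||₂,₁ + γ₂·||W||₁ ,   F = XW

* F is instantiated as the model output XW, making the objective a
  function of W alone. (Treating F as a free latent matrix optimized
  jointly is a legitimate alternative reading; XW is the default and the
  code is structured so a free-F update could be added.)
* L₁ = Laplacian of the cosine similarity between label columns
  (entries clipped at 0, relevant only for continuous targets); L₂ =
  Laplacian of a symmetrized KNN heat-kernel instance graph (k = 10,
  bandwidth = median pairwise distance — both standard defaults).
* An ℓ₂,₁-loss variant of the data term exists in the literature the
  objective descends from; the Frobenius form above is the implemented
  default.

Solver: monotone FISTA. The smooth gradient is
2Xᵀ(XW−Y) + 2α XᵀXW L₁ + 2β XᵀL₂XW with a Lipschitz step from exact
eigenvalues (d×d matrices only); the composite prox of
γ₁‖·‖₂,₁ + γ₂‖·‖₁ is exact — entrywise soft-thresholding by t·γ₂
followed by row-wise group shrinkage by t·γ₁. On objective increase the
momentum restarts and a plain proximal step is taken; the returned trace
is non-increasing. Convergence: relative objective change < 1e−7
(default), warning flag rather than exception at `max_iter`.

Hyperparameters default to α = β = γ₁ = γ₂ = 0.1 (mid-range on a
log grid from 1e−3 to 1). A per-dataset grid search with cross-validation
is the right procedure when selection quality matters and is exposed
through the `Hyperparams` knob, but it is deliberately not run inside
the default pipeline: a 4-D grid with nested folds multiplies runtime by
orders of magnitude and the planted-support experiments show the
mid-grid default already ranks informative rows essentially perfectly at
SNR 10. Features are ranked by row ℓ₂ norm (ties → lower index) and the
top k = 20 retained.

## CNN-GRU classifier

Topology (defaults): three 1-D convolution blocks over the attribute
axis of each window row — kernels 20/10/5, filters 3/6/6, stride 1,
ReLU, each followed by 2×2 max-pooling — then the per-timestamp maps are
flattened into a sequence consumed by a GRU (hidden width 20), whose
final state passes through dense layers 20 → 10 → m with independent
sigmoid outputs (m = 6). With 21 input columns the stack requires 'same'
padding (the default); 'valid' is available for longer rows. Printed
layer tables for this architecture family are internally inconsistent
about output shapes, so shapes here are always derived from standard
convolution arithmetic. A softmax output would contradict the
multi-label task; per-label sigmoids with summed binary cross-entropy
(mean over instances, probabilities clamped at 1e−12) are the only
consistent reading and are what the loss implements.

GRU cell: z = σ(W_z f + U_z h₋ + b_z), r = σ(W_r f + U_r h₋ + b_r),
h̃ = tanh(W_c f + U_c(r⊙h₋) + b_c), h = z⊙h₋ + (1−z)⊙h̃ — the update
gate at 1 holds the previous state. Everything is NumPy with
hand-derived backward passes; forward passes are tested against
scalar-loop oracles and the full gradient against central finite
differences (≤ 1e−4 relative).

Initialization: uniform ±√(1/fan-in), seeded; biases zero (so the
all-zero input maps to probability 0.5 exactly). Training: minibatch
SGD, deterministic per seed. Two recipes:

* **Corpus protocol** (TrainConfig defaults): lr 0.001, batch 150,
  constant schedule — the stated protocol for clinical-corpus scale.
* **Desk-scale recipe** (pipeline default): lr 0.2, batch 16, 120
  epochs, cosine annealing. At 100–300 synthetic records the corpus
  settings cannot leave the initial plateau; the higher rate with
  annealing trains reliably across seeds, whereas a constant high rate
  shows occasional late-epoch loss blow-ups.

Optional early stopping (patience 10 on validation loss) restores the
best weights. Decision threshold for binarizing probabilities: 0.5
(no calibrated threshold is claimed; the threshold is a config knob and
prediction is monotone in it).

## Evaluation protocol

Default split: stratified 60/40 train/test holdout; 5-fold
cross-validation is available (`split_policy="cv"`), each fold serving
as test once. (A 7:3 split is another protocol in circulation for this
corpus; the 60/40 + CV protocol is the default here and the fraction is
a config field.) Stratification is a greedy iterative assignment:
repeatedly take the label with the fewest unassigned positives and deal
its instances to the fold with the greatest remaining desired count for
that label, with exact fold-size capacities enforced. Selection,
imputation medians and z-parameters are fit on training indices only.

Metrics: bitwise accuracy ((TP+TN)/(TP+TN+FP+FN) over all instance-label
positions — identically 1 − Hamming loss) and subset accuracy are both
reported because "accuracy" is ambiguous for multi-label data; reports
always name the mode, bitwise being the default. Jaccard similarity
averages |h(x)∩y|/|h(x)∪y| over instances, scoring an empty union as 1
(the limit convention; the ratio is otherwise undefined). F1 uses
micro averaging by default (macro also reported), with 0/0 → 0.

The majority baseline predicts each label's training-majority value for
every test instance; the end-to-end checks require the trained pipeline
to beat it on micro-F1 and Hamming loss.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest sizes at which each property is cleanly
measurable: end-to-end runs use 300 records of 10 s (the acceptance
script and the end-to-end test) or 30–100 records (unit/CLI checks);
support recovery uses n = 500, d = 118, 10 informative rows at SNR 10
over 20 seeds; detector operating characteristics use 50 noisy records
(noise SD 0.05 mV) at ±50 ms tolerance; oracle comparisons use 100
random micro-instances.

## Known limitations

* The generator's simplicity means feature distributions are far more
  separable than clinical data; reported synthetic metrics do not
  transfer to real corpora.
* Delineation uses fixed windows on one lead (default II); multi-lead
  fusion and wavelet delineators are out of scope.
* The free-latent-F variant of the selection objective and the ℓ₂,₁
  data-term variant are exposed as extension points, not implemented
  alternatives.
* Training is plain SGD on CPU; the implementation favors verifiability
  (scalar oracles, finite-difference checks) over speed and is not meant
  for corpus-scale training.
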