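# Methods

`holostain` implements a virtual-staining pipeline for rare tumor-cell
detection in liquid cytology: synthetic smears of peripheral blood
mononuclear cells (PBMCs) spiked with rare HCT116-like tumor cells are
imaged by a simulated off-axis digital holographic microscope with a
parallel fluorescence channel; quantitative phase is reconstructed
numerically; a U-net learns to map phase (+ phase-gradient) images to a
stain-like rendering whose bright regions are the cancer cells; staining
quality is scored at image level (SSIM) and cell level
(precision/recall/F1/accuracy).

This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not establish.

## Optical forward model

The simulated system follows a transmission off-axis holographic
microscope: coherent illumination at wavelength λ = 532 nm, a 20× / NA 0.50
objective, and a sensor of 5.5 µm pixels (2048² by default; test
configurations use 256–512² — all physics scales with the object-plane
pitch, λ and NA, not with pixel count). The object-plane pixel pitch is
`camera_pixel / magnification` = 0.275 µm.

**Specimens.** Cells are pure phase objects with spherical-cap profiles
`peak · sqrt(max(0, 1 − (d/r)²))`. Two populations:

| parameter        | PBMC-like       | tumor-like (HCT116) |
|------------------|-----------------|---------------------|
| radius           | 3.5–5.0 µm      | 7.0–12.0 µm         |
| peak phase       | 0.6–1.2 rad     | 1.8–2.8 rad         |

Tumor peaks are capped below π so the reconstructed phase never wraps;
phase unwrapping is deliberately out of scope. A field holds 200 cells per
512×512-pixel frame (≈141 µm square) — a dense smear in which cells touch.
Tumor count per field is `max(1, round(n/(ratio+1)))` at PBMC:tumor ratios
10:1, 50:1 and 1000:1; the `max(1,·)` floor keeps one tumor cell even at
1000:1, as a screened rare-cell smear would be selected to contain.

**Monolayer overlap rule.** Where footprints overlap, the field's phase is
the elementwise **max** of the individual profiles, not their sum: fixed
cells on a slide form a monolayer, so a point's optical thickness is that
of the (taller) cell occupying it. This keeps the total phase bounded by
the tallest peak (hence wrap-free at any density), and it produces sharp
takeover creases between adherent cells — exactly the structure the
phase-gradient input channels expose to the network. Additive overlap was
considered and rejected: at smear density it drives the summed phase past
π and destroys the reconstruction contract.

**Placement.** Sequential: with probability 0.15 a cell is placed tangent
to a random existing cell (adherent clusters, the hard case for staining);
otherwise positions are uniform with a soft rejection (centre separation ≥
0.85·(r₁+r₂)), relaxed in stages down to unconstrained when the field is
crowded, because ~60–80 % areal coverage is above the random
sequential-adsorption jamming limit and a hard rejection cannot fill the
field. Per-donor biology is emulated by multiplicative jitter (σ = 0.1) on
radii and peak phases, derived deterministically from the donor label — so
held-out "unseen donors" differ systematically from training donors.

**Hologram.** The object wave `O = exp(i(φ + φ_ab))` (φ_ab a low-order
polynomial aberration: tilt, defocus, astigmatism) is propagated by the
configured defocus distance with the angular spectrum kernel and interfered
with a conjugate-tilted plane reference, `I = |O + e^{−i2π(f_x x + f_y y)}|²`,
plus Gaussian sensor noise (σ = 0.02 on a fringe amplitude of 4), clipped
at zero, optionally quantized to 8/16 bits. The conjugate tilt puts the
O-bearing cross term at +carrier in the spectrum, where the demodulator
looks.

**Carrier and band bookkeeping.** At this hardware the coherent NA cutoff
is NA·pixel/(λ·M) = 0.2585 cycles/pixel — more than half of Nyquist, so a
carrier separating the *full* NA band from DC and its twin does not exist
(the physical system undersamples the off-axis condition; common in
practice). The simulated specimens are smooth phase objects whose spectra
concentrate well inside the cutoff, so the config validates carrier
separability against an *effective* band radius `band_fraction ×
NA_band` with `band_fraction = 0.55` (b_eff ≈ 0.142 cycles/px). The
default carrier (0.25, 0.25) cycles/px then satisfies `b < |f|` and
`|f| + b < 0.5`, and lands on an exact FFT bin for power-of-two frames
(leakage-free fringes). The same b_eff is the default demodulation filter
radius and the DC-exclusion radius for automatic carrier search is 2·b_eff.

**Fluorescence.** Tumor footprints emit at unit intensity; PBMCs at
`leakage_level = 0.15` (residual excitation bleed-through); the scene is
blurred by a Gaussian PSF (σ = 4 px ≈ 1.1 µm), offset by a 0.05 background,
and corrupted by Gaussian noise (σ = 0.02). These levels make the raw
fluorescence realistically unusable as a direct training target — blurry
edges, lit PBMCs — which is what the mask-generation stage exists to fix.

## Reconstruction

1. **Demodulation** — FFT, select the +1 order (auto: strongest peak
   outside the DC-exclusion disk in the half-plane f_y > 0, ties toward
   larger magnitude then lexicographic (f_y, f_x); or the configured
   carrier), window it (hard disk by default; a soft super-Gaussian is
   selectable), shift to baseband, inverse FFT.
2. **Angular-spectrum refocus** — `H = exp(i2πz√(1/λ² − f_x² − f_y²))`
   with evanescent components zeroed. Propagation is unitary on the
   passband and forms a semigroup, both held to 1e-10 in tests.
   `z > 0` propagates toward the source: refocusing inverts the recording
   defocus (a hologram recorded `d` past focus autofocuses at `−d`).
3. **Autofocus** — coarse scan of the configured z range (default ±200 µm,
   10 µm steps), then per refinement level a ±1-step re-scan at 10× finer
   pitch; ties break toward smaller |z|; a boundary optimum raises a
   warning. The default focus metric is **minimum amplitude variance**
   (`neg_variance_amplitude`): a pure phase specimen has the flattest
   amplitude exactly at focus, which measured as the sharpest usable
   extremum here. Mean squared phase gradient (tenengrad) was evaluated
   and rejected as the default: away from focus the field develops
   near-zeros whose noisy phase inflates the gradient energy, so the
   metric is minimized (not maximized) near focus and is unreliable.
   Both alternatives remain selectable.
4. **Aberration correction** — `angle(S · conj(R) / max(|R|, 1e-12))`
   against a sample-free reference reconstructed with identical settings;
   the complex ratio is immune to 2π wraps that a literal phase
   subtraction would suffer.

With the default settings the full pipeline recovers ground-truth phase
with RMSE ≈ 0.03 rad at smear density (the residual is band-limit
truncation ringing at cell rims), comfortably inside the 0.05 rad contract
asserted in tests.

## Network inputs and targets

- **Inputs** — 3 channels ordered (gradient-x, gradient-y, phase). The
  gradients are one-pixel shift-and-subtract differences
  (`gx[i,j] = φ[i,j] − φ[i,j−1]`, first column/row zero), each channel
  min-max normalized to [0,1] with recorded, invertible parameters.
- **Masks** — Gaussian denoise (σ = 1 px) → Otsu threshold → morphological
  opening (radius 2 px) → removal of components smaller than a quarter of
  the smallest tumor footprint (≈ 508 px at default pitch) → hole filling.
  Otsu lands between the tumor signal and the PBMC-leakage/background
  modes because the inter-class contrast (~0.8) dominates the class-weight
  imbalance even at 1000:1. An empty mask is legal (a clean 1000:1 crop)
  and warns rather than fails.
- **Targets** — `0.5·normalized(phase)` outside the mask, `1.0` inside:
  a single-channel stain with cellular context at half dynamic range and
  saturated cancer cells. The 0.75 threshold recovers the mask exactly and
  is shared as one constant (`MASK_THRESHOLD`) with cell extraction, so
  the two stages cannot drift apart.
- **Crops** — 512×512 at paper scale (128×128 in reduced configurations),
  sampled without replacement on a stride-size/4 origin grid, identical
  origins applied to inputs, target and fluorescence.
- **Split** — 3:1:1 train/val/test within each (donor, ratio) stratum,
  remainders assigned train-first; unseen-donor examples carry a
  permanent `unseen` label and never enter the split.
- **Registration** — inter-tile/inter-modality translation from matched
  cell centroids: coarse shift from the mode of the pairwise-offset
  histogram (4 px bins, ambiguity between well-separated modes is an
  error), mutual-nearest-neighbour matching under that shift,
  component-wise median translation, one re-estimation after dropping
  residuals above the gate. Translation-only by design; the synthetic
  generator does not need it, but the stage is part of the tool for real
  tiled acquisitions.

## The U-net

Pure NumPy, NHWC float32, hand-written backprop (nine-shift GEMM
convolutions; gradients verified against finite differences in tests).

Geometry: four encoder blocks of (conv3×3 → ReLU)×2 with channels C, 2C,
4C, 8C, stride-2 average pooling after each; four decoder levels, each =
bilinear ×2 upsample → 1×1 projection to the skip's channel count →
concatenation with the same-level encoder features (doubling the channels)
→ (conv3×3 → ReLU)×2 mapping 2k → k/2 (a 4× per-block reduction); final
1×1 convolution to one channel. Defaults: C = 64, side 512, 3 input
channels. The reduced preset (C = 16, side 128) is the same network at
desk scale. The phase-only ablation model is identical with one input
channel. The decoder schedule is our closure of a channel-arithmetic
description that does not pin down every level; the 1×1 projection before
concatenation is what makes "concat doubles" and "block reduces 4×"
simultaneously true at every level.

Training: MAE loss `1/m Σ|y_i − f(x_i)|`, Adam (lr 1e-3, β = (0.9,
0.999)), batch 8 (reduced: 4), early stopping on validation MAE (patience
10), best-validation weights restored. He initialization, all randomness
seeded. Determinism is platform-scoped: a fixed seed reproduces a run on
one platform, bit-portability across BLAS builds is not promised.
Checkpoints are `.npz` weights plus a JSON sidecar (config, seed, history);
reloading reproduces predictions bit-identically.

Note on MAE optimization: the sign gradient moves the output by roughly
`lr` per Adam step, so short runs are step-budget-limited; the reduced
preset's 30 epochs × ~18 batches is sized for the reduced dataset.

## Evaluation

- **SSIM** — standard Wang parameterization (11-tap Gaussian window,
  σ = 1.5, K1 = 0.01, K2 = 0.03, data range 1), mean over the window-valid
  interior; cross-checked against scikit-image to 1e-6 in tests.
- **Cell extraction** — connected components (8-connectivity) of
  `stain ≥ 0.75`, minus components below the min-area floor;
  intensity-weighted centroids.
- **Cell-level counting** — per crop, ground-truth cells with centroid
  inside the crop are the census. Counting is per cell, matching how
  classification accuracy is defined: a tumor cell is TP when the stain
  covers at least 25 % of its visible footprint (a threshold consonant
  with the quarter-footprint minimum-area floor of the mask cleanup),
  otherwise FN. A single merged component thereby validates every
  adherent tumor cell it covers; a per-blob (one-to-one, centroid-gated)
  rule was evaluated and rejected because it charges a false negative for
  each additional cell in a merged cluster, capping even a *perfect*
  stainer below the accuracy the counting is supposed to measure. Each surplus component — one that stained no tumor — is
  assessed once: the nearest PBMC whose footprint it overlaps becomes a
  FP; remaining PBMCs are TN. Components explained by *margin cells* —
  cells whose centroid lies outside the crop but whose footprint reaches
  in — are ignored, because those cells belong to a neighbouring crop's
  census; full-field counting (as in the original study) has no such
  boundary effect, and ignoring margin evidence avoids manufacturing
  errors the method did not make.
- **Rates** — precision TP/(TP+FP), recall TP/(FN+TP), F1 their harmonic
  mean, accuracy (TP+TN)/total, computed once on counts pooled over the
  whole split (micro-averaging). Divisions by zero yield an explicit
  undefined flag (`None`), never a silent 0.

## Problem sizes

The unit and acceptance tests run reduced configurations chosen as desk
jobs: 256–512 px sensors, 30–200 cells per field, 128 px crops, base-16 or
smaller networks. The acceptance script runs the reduced preset end to end
(2 donors × 3 ratios × 20 crops, base 16, 30 epochs); the package's full
defaults (2048² sensor, 512 crops, base 64) reproduce the study geometry
and are exercised for shape contracts but not trained in tests. The
end-to-end accuracy check uses 2 donors × 3 ratios × 10 crops with 15
epochs; the input ablation uses the same dataset with three training seeds
at 12 epochs.

## What the synthetic data shows — and does not

The generator reproduces the *structure* of the study: two populations
separable by size and optical thickness, extreme class imbalance, adherent
clusters, aberrated/defocused holograms, imperfect fluorescence. It omits
biological texture (nuclear substructure, debris, platelets), refractive
scattering (no Mie/Rytov model), camera MTF, and stitching artifacts
beyond pure translation. Because the synthetic populations are separable
by construction, the ≥99 % cell-level accuracy of the reduced end-to-end
run bounds **pipeline correctness** — simulation, reconstruction,
preprocessing, training and counting working together — not clinical
performance on patient material.

The input ablation (3-channel vs phase-only) deserves a frank caveat. At
cell level the two models tie at the F1 ceiling in every measured
replicate, so the gradient channels do no harm. At image level, however,
the phase-only control *consistently* edges out the 3-channel model on
test SSIM at reduced scale (e.g. 0.938/0.938/0.918 vs 0.934/0.929/0.903
across three training seeds at convergence), and the ablation suite
asserts the expected direction and fails on this half. The inversion is
structural, not a bug: the stain target is by construction a function of
the phase map (0.5 × normalized phase outside the mask), and the
simulator's gradient channels are *derived* from that same phase map —
they add no information, only two noise-bearing inputs whose extra
first-layer parameters cost variance when the training set is tens of
images. The image-level benefit of gradient inputs reported on real
material rests on properties (independent edge contrast, adherent cells
ambiguous in phase alone) that this generator does not reproduce, and
that is precisely what the failing check documents.

## Known limitations

- No phase unwrapping: specimens above π of optical thickness would alias
  (excluded by construction here).
- Evanescent components are zeroed, not attenuated — inert at µm-scale
  distances but it makes unitarity exactly testable.
- The autofocus assumes a single global focal plane per field.
- Per-cell counting cannot distinguish a merged blob that truly covers two
  adherent tumors from a single over-sized detection; the simulator's
  ground truth makes the distinction testable, real data would not.
- Training the full 512/base-64 geometry in NumPy is possible but slow;
  the implementation targets the reduced preset for routine use.
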