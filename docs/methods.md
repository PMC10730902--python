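# Methods

This note documents the models, numerical choices and limitations of the
`circwave` package: what exactly is computed, which knobs matter, and what
the synthetic phantom study does and does not demonstrate.

## Non-subsampled transforms

**Haar 2D-DWT (à-trous).** The stationary decomposition uses the separable
operators S = ½(I + T_s) and D = ½(I − T_s), where T_s is a circular shift
by s = 2^(j−1) at level j. The four level products satisfy
(S_r + D_r)(S_c + D_c) = I, so the sub-bands at each level sum exactly to
the parent approximation and the full synthesis is the telescoping channel
sum A_L + Σ_j (H_j + V_j + D_j) — exact to machine precision. The ½
normalization (rather than 1/√2) is what makes the sum-reconstruction
identity hold; tests pin the level-1 channels to a brute-force periodic
convolution with the declared filter tensor products. Channel order is
fixed as `[A_L, H_1, V_1, D_1, …, H_L, V_L, D_L]` (C = 3L + 1). Periodic
boundaries make shift-equivariance exact.

**Circlet.** Realized as an isotropic radial filter bank in the frequency
domain: smooth raised-cosine steps σ_j(ρ) in log₂ radial frequency around
dyadic boundaries b_j = ν·2^(j−S−1/2) (ν = Nyquist, S stages, transition
width ½ octave); the low-pass is 1 − σ_1 and band j is σ_j − σ_{j+1}, so
the bank sums to exactly 1 at every frequency sample (amplitude partition
of unity), every filter lies in [0, 1], the DC sample belongs entirely to
the low-pass, and the channel sum reproduces the image. Band j peaks at
radial frequency ν·2^(j−S) (the recorded characteristic radius). Sub-bands
are real(IFFT(filter · FFT(image))). The construction trades the
oscillatory, center-parameterized atoms of the literature for the one
property the classification method exploits — ring-matched radial
selectivity — plus a testable exact-reconstruction contract.

**Ring-selectivity verification** uses *spectrally* annular phantoms
(inverse FFT of a thin frequency-domain annulus with random phase). A ring
drawn in image space has a spread Bessel-type spectrum and does not isolate
one radial-frequency band, so spectral annuli are the construction under
which "the argmax-energy band is monotone in the annulus radius and matches
each band's peak" is well-posed.

**CircWave** concatenates the DWT channels (first) and circlet channels;
defaults L = 2 and S = 6 give 14 channels. Stacks are bilinearly resized to
64×64 per channel (anti-aliasing on downscale); metadata records transform,
stage and band per channel.

**Half-sub-band reconstruction** ranks channels coarse→fine (approximation/
low-pass first, then detail levels by decreasing à-trous step or increasing
band radius), keeps ⌈C/2⌉ ("lowfreq") or the rest ("highfreq"),
sum-reconstructs and clips to [0, 1].

## Preprocessing

The full profile resizes to 496×512, scales to [0, 1] (integer images are
divided by their dtype maximum — 255 for 8-bit, 65535 for 16-bit), locates
the HRC, flattens, crops and denoises. HRC localization is a thresholded
intensity centroid: pixels above an Otsu threshold contribute an
intensity-weighted mean row per column, smoothed by an order-2 least-squares
polynomial across columns (columns with no above-threshold pixel inherit the
fit). This satisfies the one contract downstream stages rely on —
re-detection after flattening is flat to ≤ 2 px on phantoms with known
curvature — without reproducing any particular graph-based algorithm.
Flattening circularly shifts each column so the curve maps to its median
row. The ROI crop takes 200 px above/below the HRC row (zero-padded at
borders), resizes to 128×512, center-crops the width to the 470/512
fraction and resizes to 128×128. Denoising is non-local means with filter
strength h = 10 on the 0–255 scale (h/255 internally), patch size 7, search
window 21 — the patch geometry is a standard choice; only h is prescribed.
The ``datasetB`` profile (pre-flattened, pre-denoised sources) divides by
255, drops the first 50 columns and resizes to 128×128. The ``phantom``
profile runs normalize → flatten → recenter (HRC to the middle row, the
native-resolution analogue of the ROI crop) → denoise at the phantoms'
128-px resolution. Every applied step is recorded in the scan's provenance
and re-application is rejected.

## The synthetic phantom

A phantom B-scan is a stack of n = 8 horizontal intensity bands (fixed
reflectivity pattern, brightest band lowest — the RPE/HRC analogue) bent by
a subject-specific quadratic curve, with multiplicative speckle
(pixel × Gamma(k, mean 1), k = 1/speckle_level², default level 0.15) and a
0.8-px Gaussian blur for band-limited edges. Subject-level draws: curvature
coefficients, mean vertical position, total retinal thickness (0.38–0.42 of
the height) and per-band thickness fractions (Dirichlet, concentration 40).
Scan-level draws emulate different slice positions through the volume:
vertical offset ±2 px, curvature scale 0.85–1.15, thickness scale
0.95–1.05, fresh speckle, fresh lesions. Class morphology:

* **DME** — 1–4 dark (intensity 0.10) filled ellipses, axis ratio 0.8–1.25,
  radius 4–10 px, rejection-sampled to lie strictly inside the band region
  without mutual overlap; recorded in the lesion mask. Fluid is darker than
  the surrounding annulus on every scan by construction.
* **AMD** — 1–3 smooth Gaussian domes (amplitude 6–14 px, width 6–13 px)
  that lift the top of the lowest bright band and push the overlying layers
  upward (compressed to ≥ 1 px) — drusen-like morphology; the mask records
  the pixels whose layer assignment the dome changed.
* **normal** — bands only; the mask is all-zero.

Everything derives from `SeedSequence(spec.seed)` spawns, so equal specs
give bit-identical datasets. The phantom reproduces the *geometry* the
classification method exploits (near-0° lines for normals, circles for DME,
bumps for AMD) and subject-wise statistical structure; it does not model
A-scan physics, vendor artifacts, shadowing, or real anatomical variability.
Passing the phantom study therefore demonstrates that the pipeline is
correctly wired and that the representations behave as designed — not
clinical performance.

## Network, training and heads

The layer stack is a small NumPy implementation (channels-last): 3×3
zero-padded convolution evaluated as nine shifted BLAS products, batch-norm
(momentum 0.9, ε 1e-5; inference uses running statistics and the backward
pass treats them as constants), ReLU, 2×2 max-pool with tie-splitting
subgradients, dense, inverted dropout, softmax cross-entropy, Adam
(β₁ = 0.9, β₂ = 0.999). All parameters are float32; gradient-check tests
run the same layers in float64. Initialization is He-normal from the config
seed; shuffling and dropout draw from the same generator, so training is
bit-reproducible on a fixed thread configuration.

The feature CNN fixes the input at 64×64 so the flattened final block is
always 4·4·200 = 3200 features regardless of the channel count. BN sits
between convolution and ReLU. Model selection retains the weights with the
best validation accuracy seen within the epoch budget. The assembled
CNN + MLP network (temporary softmax head excluded) counts 3,544,888
trainable parameters.

The MSVM head standardizes features per dimension (statistics fit on the
training side only), grid-searches the kernel hyper-parameters on the
subject-wise inner folds (default RBF grid C ∈ {0.1, 1, 10, 100},
γ ∈ {10⁻⁴…10⁻¹, scale}; ties resolve to the first candidate in the fixed
enumeration order), and refits one-vs-one on the full outer-train set.
Scores are vote counts plus a bounded aggregate-margin term (< ½ vote), so
ranking is monotone in confidence and ties break by margin sum, then lowest
class index. The binary special case flips sklearn's decision sign to match
the pairwise convention.

## Cross-validation and metrics

Folds are built on subjects, stratified per class (shuffle within class,
deal round-robin), nested: each outer-train set is re-dealt into up to 4
inner train/validation splits. A leakage verifier checks that outer tests
partition the subjects and every train/validation/test triple is pairwise
subject-disjoint; the experiment loop refuses to run on a failing plan.
Scalar metrics are one-vs-rest per class (SE = TP/(TP+FN), SP = TN/(TN+FP),
PR = TP/(TP+FP), ACC = (TP+TN)/total, F1 = 2TP/(2TP+FP+FN)), macro-averaged
without class weights (the averaging scheme is a documented choice); the
plain multi-class accuracy (trace/total) is reported alongside. Zero
denominators define the metric as 0 with a warning. ROC areas use the
conventional trapezoidal integral of TPR over FPR; PR areas the step
integral of precision over recall (both cross-checked against
scikit-learn). Evaluation is per B-scan; no volume-level voting.

## Study sizes and runtime choices

The phantom study uses 5 subjects/class × 10 scans at 128 px — small enough
that the full nested 5-fold loop over three input representations runs on a
single CPU in a few minutes — and a CNN budget of 12 epochs per outer fold
(training accuracy saturates by epoch ~7 on this data; the best-validation
checkpoint is what is kept). Under these conditions the CircWave pipeline
reaches ≈0.95 macro one-vs-rest accuracy and exceeds both the original-image
and DWT-only baselines, mirroring the qualitative ordering the combined
transform is designed for.

## Interpretability experiments

Grad-CAM is taken at the block-4 ReLU output (8×8×200, the last
convolutional feature map before pooling): channel weights are the spatial
mean of the target-logit gradient, the map is ReLU(Σ w·A), bilinearly
upsampled and min-max normalized (an all-zero map skips normalization).
The lesion-focus study trains one model on original phantoms and one on
circlet *highfreq* half-reconstructions — dropping the circlet low-pass
removes the smooth layered background and leaves ring-shaped pocket rims,
which empirically (and decisively: the low-frequency half shows a far weaker
effect) is the half that draws the activation map toward the fluid pockets —
and compares the fraction of heat inside the ground-truth masks on held-out
DME phantoms with a one-sided sign test. Feature embeddings are PCA to 50
dimensions followed by t-SNE to 2 (perplexity 30 capped at (n−2)/3, PCA
initialization, 1000 iterations, fixed seed), summarized by the silhouette
score of the class labels on the embedded points.

## Known limitations

* The circlet here is a magnitude-only radial bank; center-parameterized or
  oscillatory (Bessel-phase) circlet atoms are not implemented.
* DTCW, shearlet, contourlet and ellipselet comparators are accepted
  through the transform registry but not implemented natively.
* The NumPy network is single-device and unoptimized beyond BLAS; it is
  sized for the 64×64 stacks of this study, not for large-scale training.
* Phantom results do not transfer to clinical data claims; real-data runs
  require externally downloaded datasets and are out of scope here.
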