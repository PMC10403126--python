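# Methods

## The screen model

`moascreen` treats a high-content screen as a hierarchy: plates carry
wells, wells carry imaging sites, and every well holds either one
compound or the DMSO solvent control. Compounds group into MoA classes;
the classification task is 11-way (ten MoAs + DMSO) at the site level.
The default `ScreenConfig` mirrors the emulated assay: 18 plates x 384
wells, ten MoAs with compound counts (18, 20, 33, 24, 21, 21, 23, 19,
32, 20) = 231 compounds, six replicate wells per compound (three
technical on a plate, on each of two biological-replicate plates, at
different coordinates), eight DMSO wells per plate, five sites per well,
five FL channels or six BF z-planes per site.

Layout generation is seeded stratified randomization: compounds are dealt
MoA-by-MoA round-robin across plate groups, then placed at shuffled free
wells with the constraint that a compound never reuses a coordinate
across its biological-replicate plates. (Constraint-programming layout
optimizers exist for real screens; a randomized layout is sufficient to
exercise every downstream stage and is what the tests rely on.)

### Phenotype model

Each MoA owns a unit direction in phenotype space; each compound owns a
unit identity offset. The injected mean phenotype of compound *c* at
effect size *e* is

    x_c = e * u_moa + e0 * f * v_c

with `e0` the screen's base effect size and `f = 0.35` the offset
fraction. The MoA component scales with the (possibly per-compound
graded) effect; the identity offset has fixed magnitude, so strong
compounds converge toward their MoA axis — without this, strongly dosed
held-out compounds drift laterally out of the region the classifier saw,
which is an artifact of the generator rather than a property of the
assay. DMSO maps to the origin.

Feature tables draw per-site vectors `x_c + plate_offset + N(0, 1)` in
d = 64 dimensions (32 at desk scale). Images render Gaussian-blob
"cells" (Poisson count, ~20 per 96 px field) whose per-channel
brightness, radius and density are modulated by the phenotype vector in
`n_channels + 2` dimensions (`exp(0.25 v)` for brightness, `exp(0.15 v)`
for radius/density): MoAs alter morphology, not only staining intensity.
On top come per-plate channel gains N(1, 0.1) and offsets, a fixed
per-plate low-order cosine illumination surface for BF (amplitude 0.3),
and pixel noise N(0, 0.1). All draws key on
`(seed, stream, entity index)`, making the generator bit-reproducible
and order-independent; every injected nuisance is recoverable through
`ground_truth()` / `illumination_field()` for recovery tests.

What the generator does **not** emulate: real cell morphology and
segmentation, optical PSFs, saturation and debris artifacts, dose
response, and correlations between batch effects and biology. Passing
tests therefore demonstrate that the *analysis machinery* behaves
correctly under the stated nuisance model, not that any particular
accuracy level transfers to real assays.

## Normalization

Brightfield sites are background-corrected first: subtract a
Gaussian-smoothed copy of each z-plane (sigma = kernel_side/4,
reflective boundaries). The kernel side must sit between the cell scale
and the illumination scale. On full-resolution acquisitions a ~5%-of-side
kernel does; on 32–96 px desk-scale renders the same fraction would
high-pass away the cells themselves, so desk-scale configurations use
`kernel_frac = 0.3`. Fluorescence bypasses correction.

Two strategies are then compared, selected by `PipelineConfig.normalization`:

- **DMSO plate-level**: per channel, standardize by the pooled pixel
  mean/sd of the plate's DMSO sites (pooling all control pixels, rather
  than averaging per-well statistics — the cheaper and lower-variance
  choice). Preserves relative intensity between treatments on a plate.
- **site-level**: standardize each channel by its own mean/sd. Removes
  all per-image affine intensity information; two gain-differing copies
  of a scene become identical.

Channels with sd < 1e-8 raise instead of dividing: degenerate synthetic
plates should fail loudly.

## Splitting

Splitting is at compound level only. Per MoA the shuffled compound list
is cut into five near-equal chunks (remainders distributed round-robin
across chunks over a seed-shuffled MoA order); chunk *s* is split *s*'s
test set, so the five test sets are disjoint and cover all compounds
exactly. Remaining compounds shuffle 80/20 into train/validation per MoA
(at least one validation compound when any remain). DMSO wells are
assigned once per plate — five train, one validation, two test — and
reused identically by all splits. `partition_sites` is the only gate
data flows through, which makes the no-leakage property auditable at
image level.

## Classifiers

Because the pipeline must be deterministic and CPU-sized, both models run
on a small numpy engine (`moascreen.nn`: im2col convolutions, dense
layers, ReLU, 1-D batch norm, Adam, softmax cross-entropy; all gradients
finite-difference-tested). The image backbone is a configurable stack of
3x3 stride-2 convolutions (default widths 16/32/64) with global average
pooling — the pooled vector is the penultimate embedding used downstream
— and a linear output layer. The feature benchmark is a one-hidden-layer
MLP (default 512 units, ReLU + batch norm). Larger backbones for real
data plug in behind the same `ModelConfig`.

Training: Adam at lr 3e-3 (default; 1e-3 undertrains at desk scale within
~10 epochs), batch 32, flips/90-degree-rotation augmentation for images,
checkpoint = best validation macro-F1 epoch, early stopping by patience.
Trained models record the compounds they saw so leakage is checkable.

## Profile analyses

- **Well profiles**: arithmetic mean of site vectors per well.
- **Grit**: per treated profile, z-statistic of its replicate
  correlations against its control-correlation distribution (formula in
  the README; this is the single authoritative definition in the
  package). The control moments default to the profile's own control
  correlations (`per_profile`); a `pooled` switch uses the moments of all
  treatment-control correlations instead, since either convention appears
  in practice. Undefined cases (controls, singleton groups, zero control
  spread) yield NaN with a reason, never a silent number.
- **Accuracy vs grit**: test samples sorted by grit into ten equal-count
  bins (remainder to the lowest bins), reporting per-bin mean grit and
  accuracy.
- **Sphering**: regularized ZCA fitted on control profiles,
  `W = (Σ + λ (tr Σ / d) I)^{-1/2}` by symmetric eigendecomposition; the
  trace scaling makes λ unitless. Small λ whitens the controls; large λ
  degenerates to centering plus uniform scaling. Note whitening rescales
  but does not remove plate *mean* differences: with between-plate
  variance fraction ρ along an offset direction, the whitened fraction is
  still ρ — silhouette drops substantially (≥ half in the diagnostic
  conditions) but not to zero, matching the partial improvements seen in
  practice.
- **mAP**: controls excluded; each well ranks all other wells by cosine
  similarity (ties broken by stable well order); AP = mean precision at
  the ranks of same-MoA wells; labels with a single well are dropped with
  a warning.
- **Diagnostics**: cosine similarity distributions within vs across MoA
  (separation = difference of means), and the plate x plate Pearson
  matrix of per-plate mean control features (split-pooled).

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → split → train (BF CNN,
FL CNN, CP MLP per split) → evaluate → profile → match under one run
directory. Images travel as per-site multi-page TIFFs, tables as CSV
(read back with round-trip float parsing), metrics as JSON with sorted
keys. Each stage's outputs are checksummed into `manifest.json`; resume
skips stages whose outputs are intact and whose upstream did not rerun,
and recomputes a deleted stage plus everything downstream. Seeds are
split into layout/render, split and training streams. Because every
computation is seeded numpy on one CPU, identical configs reproduce the
metric files byte for byte.

## Reference study conditions

The self-validation protocols (`moascreen.experiments`) use a two-plate,
ten-MoA screen with ten compounds per MoA, 48 px sites, two sites per
well, 32 features:

- **Graded recovery**: per-compound effect multipliers cycle
  (0.5, 1, 2, 4, 8) twice per MoA — two compounds per level, so each
  level stays represented in training when one is held out — at base
  effect 0.75, chosen so the strongest level does not saturate accuracy.
  CNNs are trained on all five splits of three seeds and test predictions
  pooled (~3600 site records). Measured: grit and mAP strictly increasing
  in injected level (Spearman 1.0), ten-bin accuracy and AP increasing in
  mean grit (Spearman ≥ 0.94 across seed triples).
- **Chance control**: the same screen at effect 0; accuracy within 0.05
  of 1/11, macro-F1 inside its prediction-permutation band (macro-F1 of a
  collapsed classifier falls *below* 1/11, so the band comes from
  permuting predictions, not from the nominal rate), mAP inside its
  label-permutation null.
- **Sphering diagnostic**: 10 plates x 100 control wells, d = 20
  (n = 50 d), plate offset sd 2.0 — pronounced enough that the
  plate-cluster silhouette is well off its noise floor (~0.45) before
  correction; λ = 1e-3 sphering reduces it by ~58% and leaves the control
  covariance within Frobenius distance ~0.02 of identity (bound 0.1 d).

Problem sizes were chosen so the full suite and the acceptance script
each run in minutes on a single CPU.

## Known limitations

- The numpy engine trains small networks only; it has no GPU path and no
  convolutional batch norm.
- Image phenotypes live in an (n_channels + 2)-dimensional space; with
  ten MoAs this is deliberately crowded (MoA pairs can be nearly
  collinear), producing realistic per-class confusability — but it means
  image-route accuracy is bounded away from 1 even at large effect.
- The grit definition here is one member of a family (per-profile vs
  pooled control moments); results are reported for the per-profile
  default.
- Compound identifiers are formed as `<moa>_<k>`; MoA names containing
  underscores would break the reverse mapping and are rejected at
  configuration time.
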