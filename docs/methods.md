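# Methods

## The scoring model

`nashscore` reads a trichrome-stained liver WSI the way a pathologist
does: local recognition first, then aggregation to a per-biopsy score.

**Tile geometry.** Slides are 8-bit RGB TIFFs at 0.44 µm/px. Tiles are
299 px squares on a non-overlapping grid with a top-left origin and
half-open extents `[x, x+299)`; edge remainders are discarded rather than
padded, because the classifiers expect a fixed field of view. Ballooning,
inflammation and steatosis are read at 0.44 µm/px (tile side 131.56 µm);
fibrosis at 1.32 µm/px (tile side 394.68 µm) on a raster produced by a 1:3
area-average downscale — area averaging was chosen over decimation or
interpolation as the least aliasing-prone reduction. Tiles whose
saturation-based tissue fraction falls below `min_tissue = 0.05` are
recorded as *ignore* without inference; biopsies typically occupy a small
part of the glass.

**Tile classifiers.** One CNN per feature, each with the feature's numeric
classes plus one ignore class (artifacts, glass, fragment edges, pen
marks). The packaged backbone is a compact four-block convolutional
network (3×3 edge-padded convolutions, ReLU, 2×2 max-pooling; channels
16/32/48/64; global average pooling; softmax head) implemented in numpy
and sized for single-CPU training. Tiles are downscaled to the network
input (96 px for the high-resolution features, 128 px for fibrosis —
fibrosis structures are thin, and at 96 px the stage-1 perisinusoidal
fibers lose contrast). Training uses Adam with step learning-rate decay
(×0.3 at 60% and 85% of the epoch budget; without decay the 0/1 and 2/3
stage boundaries oscillated between epochs), class-balanced sampling with
replacement, and flip/rotate augmentation only, since histology has no
canonical orientation. Labelled tiles are split 95/5 into train and
validation, stratified per class. Warm-starting from a prior checkpoint
(the transfer-learning mechanism) copies all shape-compatible weights and
re-initializes the head when the class count differs.

**Class activation maps.** Gradient-weighted CAM on the last
convolutional stage: channel weights are the spatial mean of the target
logit's gradient, maps are ReLU'd, upsampled to the tile and min-max
normalized. A spatially constant input yields exactly constant activations
(edge padding), and the map is defined as all-zero in that case.

**Aggregation.** A feature map is reduced to `2K+1` numbers: the mean
ignore-renormalized class probabilities over usable tiles, the mean
per-tile weighted class, and one *spatial entropy* per class. A tile is
usable when it was classified and its ignore probability is ≤ 0.5; the
per-tile weighted score drops the ignore mass and renormalizes, keeping
scores on the pathologist scale. The per-class entropy is the Shannon
entropy of how that class's probability mass distributes across tiles,
normalized by `ln T` so slides of different sizes are comparable: 0 means
focal (one tile carries all the mass), 1 means diffuse. This is the
reading of "entropy per class" that yields exactly one number per class
and encodes the spatial pattern (e.g. bridging fibrosis is focal,
steatosis is diffuse); it is isolated behind `class_entropy` so an
alternative definition can be swapped in. Slides with fewer than 5 usable
tiles are flagged low-confidence; slides with none are flagged missing and
excluded from ANN training with a warning.

**Scoring ANNs.** One regressor per feature: input `2K+1`, two hidden
ReLU layers (16 and 8 units), one output unit through `S·σ(z)` so the
score is continuous in `[0, S]`. Inputs are standardized with training
moments. Training minimizes MSE with full-batch Adam (lr 0.01, 600
epochs) and an L2 penalty of 1e-3 on the weights; with a few dozen
training slides an unregularized long run reaches near-zero training MSE
but behaves pathologically off the training manifold, which the penalty
and a 3-member seed ensemble per fold suppress. Evaluation scores come
from score-stratified 4-fold cross-validation over slides; each slide is
predicted exactly once by the fold that did not train on it. Fresh slides
are scored by averaging all fold members.

**Evaluation.** MAE is computed on the continuous predictions; κ and
precision/recall/F1 require categories, so predictions are discretized by
round-half-up, clipped to the score range. Quadratic weights are
normalized by S² — the normalization cancels between numerator and
denominator, which the tests assert. When both raters are constant and
equal, the expected-disagreement denominator vanishes and κ is defined
as 1. Support weighting makes weighted recall equal overall accuracy, a
known identity asserted on random instances. The NAS row sums the discrete
truths and the continuous component scores (discretized to 0–8 for κ and
P/R/F1).

**Classical baseline.** Collagen area by color deconvolution: per-pixel
`OD = −log10((I+1)/256)`, least-squares unmixing onto unit stain vectors
(collagen, cytoplasm, and an orthogonal third when only two are given),
collagen-channel threshold 0.15 OD within tissue. The shipped stain
vectors match the synthetic palette and are meant to be overridden per
staining batch — stain vectors are lot-dependent in practice. Group
contrasts use two-sided Mann–Whitney U against the score-0 control with
Holm correction; ordinal groups and skewed area distributions argue for a
rank test.

## The synthetic-histology generator

The generator emulates a Masson-type stain: pink-beige tissue with
multiplicative speckle and low-frequency shading, near-white macrovesicular
vacuoles, dark-purple inflammatory cell clusters, enlarged pale ballooned
cells (13–18 µm radius, hydropic swelling) with a central dark nucleus,
and blue-green collagen whose hue is well separated from the counterstain
so color deconvolution has signal.

Per-slide ground truth derives deterministically from the generative
parameters through the Kleiner rules: steatosis via the printed area
thresholds (boundaries at exactly 33% and 66% resolve to the lower score),
inflammation via foci per 200× field — the "field" is modelled as a 660 µm
square, a stated convention since the field area is conventionally
implicit — ballooning none/few/many → 0/1/2 with generator thresholds 1–3
ballooned cells per mm² = few and > 3 = many (the verbal scale carries no
numbers; the generator must pick something monotone), and the fibrosis
stage verbatim. Cohort sampling keeps each parameter strictly inside its
score's interval, so a sampled slide's score is never boundary-ambiguous;
inflammation focus counts are chosen as integers whose implied per-field
density lies inside the target band, making the rendered count and the
recorded score exactly consistent.

Fibrosis is one topology class per slide (no mixtures — keeps ground truth
unambiguous for parameter recovery), painted per low-resolution tile
region: stage 0 sparse round portal specks with a widely varying baseline
area (0.2–2.8% of tissue, emulating nonspecific portal collagen); stage 1
adds thin perisinusoidal fibers (4–5.5 µm × 50–90 µm) totalling only
0.15–0.45% extra area — deliberately inside the baseline variability, so
collagen *area* carries almost no stage-1 information while the fiber
*morphology* does; stage 2 periportal rims (annuli) to 2.0–3.2% total;
stage 3 rims plus straight bridging streaks between rim centers to
3.0–4.6%; stage 4 broad rings enclosing tissue nodules to 5–8%. This
reproduces the mechanism by which an area-based classical measure misses
early fibrosis that a morphology-based classifier detects.

Vacuoles are added last with droplet radii that shrink as the remaining
area deficit shrinks, so the rendered vacuole fraction lands within a few
pixels of the target (and within 0.02 for slides of ≥ 9 tiles). Droplet
centers avoid inflammatory foci, ballooned cells and collagen pixels —
fat does not displace fibrotic bands — which keeps the co-occurring
morphology legible and the collagen mask meaningful on fatty slides.

Training tiles are rendered with *mixed* backgrounds by default: random
amounts of the non-labelled features are painted alongside the labelled
morphology, because classifiers trained on clean single-pathology tiles
mark real mixed-pathology slide tiles as ignore. Low-resolution training
tiles are rendered with speckle noise scaled by 1/3, matching the noise
spectrum of the 1:3 area-averaged slide raster (an unmatched noise
spectrum is a genuine domain gap: with it, stage 0/1 discrimination
learned on tiles did not transfer to slides). Observer noise, when
requested, perturbs a recorded score by at most ±1 with probability
derived from a normal deviate of the given SD, clipped to the range.

**What the generator does not emulate:** nuclei-level cytology, real stain
variability between laboratories and scanners, sectioning artifacts,
mixed fibrosis topologies within one slide, microvesicular steatosis, and
the pathologist's holistic context. Passing tests therefore demonstrate
that the pipeline recovers scores when the tile morphology genuinely
carries them — they do not certify performance on real biopsies.

## Study conditions and problem sizes

The packaged end-to-end run uses 120 noiseless slides of 1794×1794 px
(0.62 mm² of tissue, 6×6 high-resolution and 2×2 low-resolution tiles), a
uniform score mix, and desk-scale CNN budgets (64 tiles/class, 14 epochs
at 96 px for ballooning and inflammation; 24/class, 10 epochs for
steatosis; 80/class, 24 epochs at 128 px for fibrosis). Under these
conditions the out-of-fold recovery is: steatosis MAE ≈ 0.04 and ρ ≈ 0.97,
fibrosis MAE ≈ 0.27 and ρ ≈ 0.93, ballooning ρ ≈ 0.79, inflammation
ρ ≈ 0.70. The two count-driven features are limited by counting
statistics, not by the classifiers: at 0.62 mm² a "few"-ballooning slide
carries 1–2 discrete cells among 36 tiles and inflammation foci are
Poisson-placed, so adjacent burden levels genuinely overlap at the slide
level. Larger slides raise both signal and classifier noise
proportionally; only a lower tile false-positive rate would lift these
correlations materially.

## Numerical choices and degenerate inputs

- Probability vectors are softmax outputs and sum to 1 within 1e-6;
  weighted scores are NaN (flagged missing) when ignore mass exceeds 0.5.
- `class_entropy` is 0 for a single usable tile or zero class mass.
- κ levels must cover both raters; out-of-level values are rejected.
- TIFF resolution is stored as an exact limited-denominator rational, so
  µm/px round-trips to ~1e-9.
- Grids on slides smaller than one tile are empty with a warning; slide
  specs smaller than one tile are rejected.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; reruns with the same seeds are bit-identical.

## Known limitations

- The packaged backbone is CPU-sized; large pretrained backbones (and true
  ImageNet initialization) are out of scope, though the warm-start
  mechanism is implemented and tested.
- The ignore class is folded into scoring by renormalization; whether an
  ignore-dominated tile should instead abstain entirely is a judgment the
  renormalization threshold (0.5) only approximates.
- The entropy definition and the 2K+1 aggregation layout are the package's
  reading of "average, weighted class, entropy per class"; both are
  isolated so alternatives can be swapped without touching the scoring ANN.
- Synthetic-to-real transfer is untested by construction; see the
  generator caveats above.
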