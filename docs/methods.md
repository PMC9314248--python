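# Methods

## The pipeline

The package implements a weak-supervision strategy for histopathology in
which the expensive expert step is moved from per-tile annotation to
per-cluster review. A self-supervised encoder embeds tiles; K-means groups
them; a pathologist (here: a recorded integration map) merges clusters that
depict the same morphological finding, discards clusters that mix findings,
and labels the rest; a classifier is then fine-tuned from the encoder on
those weak labels. Case-level finding frequencies feed a diagnosis model
and survival analyses. An ablation ("non-integrated") skips integration and
transfer learning entirely and uses nearest-centroid cluster frequencies as
case features.

## Contrastive encoder

Momentum contrast with a FIFO negative queue. Defaults follow the original
recipe where it states them: queue size K = 4096, key momentum m = 0.99,
temperature t = 0.1, Adam at learning rate 1e-4, augmentation by random
horizontal flip and rotation uniform in ±20°, then a 224-px centre crop;
features are 128-d and L2-normalized (normalisation is required by the
temperature-scaled dot products and is the adopted method's convention).
Two independently augmented views of one tile form the (query, positive)
pair. The queue is initialised with random unit vectors so its length is
always exactly K; real keys replace the oldest entries first. Epoch count
and batch size are not specified upstream and are plain config.

The backbone is a configurable stack of 3×3 stride-2 conv + ReLU blocks
with global average pooling and a dense projection, written in numpy with
manual backpropagation (gradient-checked against finite differences to
relative error < 0.5%). The tested desk profile uses 3 blocks
(16/32/64 channels) on 32-px inputs with K = 256 and batch 64 — it trains
on 2000 tiles in under a minute on one CPU core. An 18-layer-class
backbone and 224-px crops remain expressible through `SSLConfig`, but are
not what the test suite exercises.

Rotation of a tile leaves corners uncovered; a 280→224 crop removes them,
but desk-scale 32-px tiles have no crop margin, so uncovered corners are
filled with the tile's mean colour. Classifier fine-tuning therefore uses
no geometric augmentation by default; instead it applies stain-colour
augmentation (per-image channel gain 1 ± 0.3 and brightness shift ±0.3·90),
the standard histopathology device for stain invariance. Both choices are
config switches.

## Tiling

Background is a pixel with all three 8-bit channels strictly above 220
(`>220`, so a 220 pixel is tissue). Exclusion thresholds are strict: a tile
is dropped when its background fraction exceeds 0.9 (principal pretraining
set) or 0.7 (supplemental/utility). The per-slide cap of 300 applies after
background filtering, as a seeded uniform subset. Grid coordinates are
0-based, top-left origin, half-open extents; partial edge tiles are
dropped (fixed-size model input). Stride = tile_size × (1 − overlap).

## Synthetic cohort: what it emulates, and what not

Each slide is a patchwork of rectangular texture regions on a fixed grid
(largest-remainder quantisation makes area bookkeeping exact); textures are
oriented band-pass noise over a base colour, deterministic given
(class, seed). Magnifications 20×/5×/2.5× are exact block downsamples
(factors 1/4/8). Per-slide stain jitter multiplies channels by 1 ± 0.35 and
shifts brightness by ±0.35·90, leaving the ground-truth mask untouched.

Case-level structure: a latent disease group (50/50) sets a Dirichlet prior
over class composition x; the diagnosis label is Bernoulli(sigmoid(w·x +
b)); survival is exponential with hazard h0·exp(β·x) and administrative
censoring at the follow-up horizon (1825 days; h0 = 1/6000 per day gives a
realistic ~30% event rate). Defaults encode the scientifically interesting
regime:

* **the decisive finding is rare** — class 0 has Dirichlet weight 2.0 in
  the UIP-like group and 0.2 in the other, and carries essentially all of
  the diagnostic signal (w = (25, 0, 0, 0), b = −2.5; the label-model AUC
  ceiling from true composition is ≈ 0.92). Rarity is the point: K-means on
  a mixed pretraining set almost never yields a majority cluster for a
  class at ~8% prevalence, so whole-set cluster review cannot label it, and
  a per-case clustering of an enriched supplemental cohort (Dirichlet
  (8,2,2,2)) is needed — the mechanism the integrated pipeline has and the
  ablation lacks;
* **staining variation is comparable to between-class colour separation**
  (jitter 0.35 vs palette distances ≈ 60–100), so colour is an unreliable
  cue and cluster assignments of fresh slides scatter, while class identity
  stays recoverable from band orientation/frequency — the rare class is
  the most strongly banded (0.28 cycles/px).

These settings were fixed at design time from component diagnostics
(cluster-majority counts, per-class confusion on held-out cohorts) and then
frozen; across master seeds 0–3 and 5 the integrated pipeline beat the
best-k non-integrated baseline in 5,5,5,4,5 of 5 replicate cohorts.

Not emulated: nuclei or stain physics, irregular region shapes, spatial
correlation between findings, scanner/batch structure beyond a single
per-slide colour transform, multi-slide cases (the generator emits one
slide per case; aggregation still sums over slides when given several).
Passing tests therefore show the pipeline's machinery and its comparative
logic are sound — not that it would reach any particular accuracy on real
tissue.

## Cluster integration

The integration map is JSON: every cluster id maps to a scheme class or the
sentinel `EXCLUDED`; validation rejects missing, duplicate or unknown ids
and unknown classes. A cluster receives exactly one class — mixed clusters
must be excluded, which enforces the method's rule. "other" is a trainable
class (it appears as an output class in finding maps). On synthetic data
the pathologist is stood in for by an oracle map: each cluster takes its
majority ground-truth class, and clusters whose majority covers < 0.7 of
members are excluded (the purity threshold plays the human "this cluster
mixes findings" judgement; configurable). Supplemental per-case enrichment
clusters each enriched case independently (default k = 10 per case in the
module, 6 in the desk-scale experiment) and merges the reviewed labels into
the master dataset; a corrections table (relabel/remove with audit log)
covers the manual-correction pass.

The default finding schemes list the published classes per magnification;
the 5× list includes "pale", which the source text describes but omits from
its own enumeration — the discrepancy is deliberate and documented here.
Whether "other" tiles count as a diagnosis feature is ambiguous upstream;
they are included by default and excludable by config.

## Diagnosis and statistics

Case features are finding *proportions* (counts are confounded by specimen
size); at 5× the "complete normal" count is recorded but removed from the
denominator. The stratified split reproduces 126/54 at n = 180 with
per-class prevalence differing by at most one case. The random forest
follows the regressor convention — the score is the mean tree vote, already
in [0, 1] — with 500 trees and √p features per split; the SVM uses an RBF
kernel with probability calibration (hyperparameters are not specified
upstream; these are the field's defaults). AUC is the pairwise concordance
probability with ties counted ½, computed via midranks; its CI is DeLong by
default (bootstrap optional). Model comparison resamples cases (the
exchangeable unit), stratified by class so every replicate contains both
classes, and reports the fraction-based two-sided p = 2·min(P(Δ≤0),
P(Δ≥0)); measured type-I error at α = 0.05 is 0.065–0.08 over 200 null
simulations, inside the accepted band. Sensitivity/specificity call a case
positive at score ≥ threshold (default 0.5).

## Survival

Kaplan–Meier and Cox fits are delegated to lifelines; Efron tie handling is
lifelines' default and the package's choice (the source is silent). Horizon
survival is reported at 1826 days ≈ 5 years. The collinearity filter is
deterministic: repeatedly find the pair with the largest |Pearson r| at or
above the threshold (default 0.7 — "high correlation" is not quantified
upstream) and drop the member with the larger mean absolute correlation to
the others, ties going to the later column; constant covariates are dropped
first. The published exclusion list is data-dependent and deliberately not
hard-coded. Cox covariates are proportions (not standardized); the pipeline
applies a small ridge penalty (0.1) at the 20-case demo scale to keep the
fit well-posed, and subgroup analyses skip strata with fewer events than
covariates.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng` (per-stage seeds are spawned from the pipeline
seed, so changing the diagnosis seed cannot alter tiling artifacts);
K-means uses k-means++ with 10 restarts; nearest-centroid distances are
rounded at 1e-9 before argmin so exact ties go to the lowest cluster id;
argmax tie-breaks in classification follow scheme order; L2 normalisation
guards against zero vectors with a 1e-12 floor. Deterministic stages (tile,
aggregate) reproduce byte-identical manifests under rerun, which the run
manifest verifies via SHA-256 artifact hashes.

## Problem sizes used by the test suite

Representation checks train on a 2000-tile, 4-class texture bank for 10
epochs; the integrated-vs-ablated comparison uses one frozen pretraining
chain (40 slides, 12 contrastive epochs, k = 16, 12 enriched supplemental
slides, 20 fine-tuning epochs) evaluated on five fresh 100-case cohorts
against best-k ∈ {4, 8, 20}; the end-to-end demo runs 20 cases. These sizes
are the package's desk-scale study conditions; every full-scale parameter
stays reachable through config.
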