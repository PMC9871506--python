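# Methods

`canopydx` reimplements a UAV-multispectral diagnosis pipeline for N/P/K
deficiency in potted *Ligusticum chuanxiong*: radiometric calibration,
SVM canopy masking, a 20-variable spectral feature set, information-value
(IV) variable screening, and an imbalanced three-class classifier protocol,
evaluated over a stress time series at two flight altitudes. Because no
field imagery ships with the package, every stage is driven and validated
by a synthetic scene generator whose statistical structure matches the
assumptions the analysis makes.

## Synthetic trial model

Each acquisition is a grid of square pot regions (30 cm) on a soil
background, imaged in five bands (B 450, G 560, R 650, RE 730, NIR 850 nm)
at a ground sampling distance of 0.265 cm/px (5 m above ground) or
0.529 cm/px (10 m). Canopies are filled ellipses with area equal to the
configured cover fraction and a jittered axis ratio (0.87–1.15 at constant
area); per-pixel canopy cover is computed on a 4×4 subgrid, so edge pixels
mix canopy and soil linearly and a coarser GSD yields a larger mixed-pixel
fraction (perimeter scales with GSD, area does not). Two calibration panels
(nominal reflectance 0.10 and 0.90) are rendered into every scene.

A canopy pixel of pot *j* in class *c* on stress day *t* is

    x = mu_c(t) + delta_j + eps,   eps ~ N(0, sigma_px^2 I5),  delta_j ~ N(0, sigma_pot^2)

clipped to [0, 1], where `delta_j` is a per-pot brightness offset shared
across bands (illumination / vigour) and `eps` is independent sensor noise
per band. Defaults: `sigma_px = 0.01`, `sigma_pot = 0.005`, 48 pots per
treatment class. The clipping rate at these defaults is far below 1%.

Class band-mean trajectories are piecewise linear in day: zero effect
before a class-specific onset (ND day 15; PD and KD day 22), ramping to a
plateau at day 38. Directions follow the physiology the diagnosis relies
on: nitrogen deficiency raises visible reflectance (pigment loss), lowers
NIR and thins the canopy (cover 0.55 → 0.35); phosphorus/potassium
deficiency darkens the visible bands and slightly raises NIR, so NIR/visible
ratio indices (GRVI, RVI, GNDVI…) rise, with a small cover reduction. At
the day-38 plateau the standardized CK-versus-deficient separation on the
ratio indices is 4–7 within-class SDs. Recovery groups (NS/PS/KS) track
their parent until re-supplementation at day 30 and then relax linearly to
the control profile by day 58; they are generated but excluded from
classifier training by default, since their role in the modelling protocol
is not defined.

The fast path (`generate_feature_dataset`) samples the same noise model per
pot over the pure-canopy pixel count the rendered geometry would contain,
sharing the pot-offset random streams with the rendering path; a paired
test confirms the two paths agree within pixel-noise scatter.

What the generator does *not* emulate — and therefore what passing tests do
not establish about field data: radiative transfer (leaf optics, canopy
structure), illumination and weather variation, orthomosaic geometry,
spatially correlated soil texture, and a full-rank within-class covariance
(pot-level variation acts through a single shared brightness factor, so the
synthetic feature covariance is much lower-rank than real canopies).

## Feature set

Five band means plus fifteen vegetation indices: NDVI, RVI, EVI, DVI, RDVI,
SAVI, GNDVI, NDRE, OSAVI, GRVI, LCI, NDWI, BNDVI, BVI, BRVI. VI means are
computed pixel-wise and then averaged over the canopy mask; the
index-of-mean-bands alternative is available behind `pixelwise=False` (the
two differ by Jensen bias on ratio indices). Undefined pixels (zero
denominators) are excluded from that sample's mean and counted, never
zeroed. RDVI defaults to the renormalised form (NIR−R)/√(NIR−R) used by
the source protocol, with the common literature form (NIR−R)/√(NIR+R)
behind `rdvi_form="literature"`. NDWI ≡ −GNDVI is computed deliberately:
detecting that redundancy is the screening stage's job. The canopy mask
comes from a linear SVM on standardized 5-band pixel vectors (fast enough
for megapixel scenes; the simulated soil/canopy contrast is linearly
separable), with held-out pixel accuracy reported.

## Variable screening

IV with 10 equal-frequency (quantile) bins; duplicate quantile edges from
ties are merged and recorded. Per-bin zero counts of either class are
raised to 1 before the weight-of-evidence term; the totals are *not*
recomputed — the adjustment rule speaks only of the per-bin counts, and
keeping totals fixed makes IV additive over bins. Quantile binning makes IV
invariant under strictly monotone transforms and IV ≥ 0 holds term-wise.
IV is computed twice (ND positive; PD∪KD positive); variables are ranked by
the larger of the two (a `sum` rule is available), ties broken by name, and
greedily pruned at |Pearson r| ≥ 0.9 against already-kept variables.
Screening pools the dataset it is given; stratify upstream to screen per
acquisition. Equal-width binning is available via `scheme="width"`.

## Classification protocol

Stratified 7:3 split → standardize → PCA retaining 95% cumulative variance
(integer override available) → SMOTE in PCA space to equal class counts
(k = 5 neighbours, seeded; training rows only) → classifier. Six
algorithms: KNN, LR, Gaussian NB, SVM, decision tree, random forest, with
small default grids (KNN k ∈ {3,5,7,9}; LR and SVM C ∈ {0.1,1,10}; DT depth
∈ {3,5,∞}; RF trees ∈ {100,300}) tuned by 5-fold stratified CV maximising
macro one-vs-rest AUC; scaling, PCA and SMOTE are refitted inside every
fold. Metrics come from one-vs-rest confusion counts — precision
TP/(TP+FP), recall TP/(TP+FN), F1 their harmonic mean — with an undefined
precision (no positive predictions) reported as 0 and flagged. Macro AUC is
the unweighted mean of per-class one-vs-rest ROC areas, computed from
predicted probabilities or, for margin classifiers without calibrated
probabilities, from decision margins (any monotone score gives the same
ROC). Everything is averaged over ten random splits with seeds
`base_seed … base_seed+9`; grid search re-runs inside every repeat by
default (`reuse_grid` gives the cheaper variant).

## Numerical choices and degenerate inputs

Reflectances are clipped to [0, 1] after calibration and after noise
addition. A constant variable discretises to a single bin with IV 0 and a
warning; zero-variance columns are droppable in screening. Scenes are
stored as float32 multi-band TIFF with a JSON sidecar (layout, labels,
truth); panel verification tolerates float32 rounding. Percent changes of
growth indicators are rounded half-up to two decimals via decimal
arithmetic, matching the convention of the summary tables they reproduce.

## Problem sizes

The test suite and the acceptance script run the full-size day-38 table
(192 samples: CK 48, ND 48, PD∪KD 96) for classification checks, reduced
pot counts (4–10 per class) for scene-rendering checks, and Monte-Carlo
draws of 150–300 pots per class for distributional checks; these sizes put
sampling error well below the asserted tolerances while keeping the default
run fast.

## Known limitations

- The shared-brightness pot effect makes the synthetic feature covariance
  low-rank; the |r| ≥ 0.9 pruning therefore keeps only 3–4 variables
  (against 10 on the original field data), and at some seeds the subsequent
  95%-variance PCA folds them to two components, where occasional extreme
  PD∪KD pots cross the ND boundary (mean ND precision ≈ 0.96 instead of
  1.0). Macro AUC stays ≥ 0.99 throughout.
- The canopy mask classifier is trained on truth-sampled pure pixels;
  real deployments need hand-labelled pixels and will see lower masking
  accuracy near canopy edges.
- The printed-form RDVI is undefined wherever NIR ≤ R; such pixels are
  excluded from the sample mean, which on noisy near-zero-DVI canopies
  biases RDVI upward. Use the literature form when that matters.
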