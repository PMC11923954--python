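# Methods

This note documents what each stage of `pgccscreen` computes, the default
parameters and why they were chosen, what the synthetic fixtures do and do
not emulate, and the package's known limitations.

## 1. Image quantification (`pgccscreen.imaging`)

A well is a `(3, H, W)` image: channel 0 nuclei (Hoechst-like), channel 1
live-cell cytoplasm (calcein-AM-like), channel 2 dead-cell nuclei
(ethidium-homodimer-1-like).

**Segmentation** is a three-step classical pipeline:

1. Gaussian smoothing (`smoothing_sigma = 1` px) of the nuclear channel;
2. global Otsu threshold (or a fixed threshold) followed by hole filling;
3. distance-transform watershed to split touching nuclei
   (`split_min_distance = 7` px between seed maxima), with optional border
   exclusion and an area gate (`min_area = 40` px², `max_area = None`).

Otsu assumes a bimodal histogram; a blank well violates that and Otsu will
happily "find" noise. The guard `max_foreground_fraction = 0.45` rejects a
threshold that would label nearly half the image as foreground and returns
zero nuclei instead — for plate imaging, foreground well above that
fraction is not plausible tissue but a failed threshold.

**Viability**: a nucleus is dead iff its mean dead-channel intensity
exceeds `dead_intensity_threshold`; otherwise live. The default in the
fixture parameter set is 20 % of the dead-channel amplitude, i.e. well
above background but far below a genuinely stained nucleus.

**PGCC calling**: among live nuclei only, PGCC iff nuclear area ≥
threshold (inclusive). The threshold is calibrated per experiment as
`multiplier × median(control nuclear areas)` with `multiplier = 2`
(doubling in area is the conventional operational definition of nuclear
enlargement for PGCCs; a warning is emitted when fewer than 20 control
nuclei support the median, and multipliers ≤ 1 are rejected as they would
call the majority of normal nuclei). Dead cells are excluded from both the
PGCC and the non-PGCC tallies; "total cells" throughout the package means
total *live* cells.

## 2. Screen analytics (`pgccscreen.screening`)

Per plate, compound-well counts are normalized by the arithmetic mean of
the control wells (median available as an option for outlier-heavy
controls). A zero control mean flags the plate's wells as excluded (NaN)
rather than raising, so one bad plate cannot abort a campaign.

The modelling response is `y = log2(norm_pgcc + 1e-3)`. The log2 makes
fold changes symmetric and additive; the pseudo-count `1e-3` keeps wells
with zero surviving PGCCs finite while placing them (≈ −10) clearly below
any well with survivors. The transform is strictly monotone, hence
rank-preserving and invertible.

Hit categories use inclusive boundaries: `total_inhibited`
(norm_total ≤ 0.5), `pgcc_enriched` (norm_pgcc ≥ 2), `pgcc_reduced_2x`
(norm_pgcc ≤ 0.5), `pgcc_reduced_10x` (norm_pgcc ≤ 0.1) and
`dual_inhibitor` (pgcc_reduced_2x ∧ norm_nonpgcc ≤ 0.5). Categories
overlap by design (10× reduction implies 2×).

## 3. Molecular features (`pgccscreen.features`)

Structure channels: MACCS keys (RDKit; the unused bit 0 is dropped,
leaving 166), ECFP6 (Morgan radius 3, folded to 1024 bits), and an 881-bit
substructure-key fingerprint following the published PubChem sectional
layout (element counts, ring counts, bonded-pair patterns, SMARTS keys).
The PubChem implementation is a **dialect**: no library in this stack
computes the CACTVS server-side keys, so positions whose definitions are
not reproduced here are fixed at zero. It has the exact length, layout and
substructure-key character of the original but is not bit-compatible with
PubChem server output; it should be compared within this package only.

All seven non-empty concatenations of the three fingerprints (fixed order
MACCS, PubChem, ECFP6) plus two text-embedding sets (1536- and
3072-dimensional vectors of the compound description) give nine feature
sets. Compounds whose SMILES fail to parse, or with empty descriptions for
embedding sets, are dropped with an audit trail rather than imputed.

## 4. Benchmark (`pgccscreen.models`)

Seven families × nine feature sets = 63 configurations, all evaluated
under one shared `CVPlan`: by default 10 rounds of a random balanced
10-fold partition. Sharing the plan pairs every model comparison by round
and fold. Scoring: per-fold Pearson correlation between predicted and
actual `y`, averaged per round; a configuration's headline is the median
round score. Folds where a model predicts a constant (correlation
undefined) score 0 with a warning; a fit exception marks the configuration
failed rather than aborting the grid.

Hyperparameters are scikit-learn defaults with three deliberate,
compute-conscious exceptions sized to this package's problem scale
(hundreds of compounds, up to 3072 features, one CPU):

* **Random forest** uses `max_features="sqrt"`. Scanning all features at
  every split is prohibitive on wide fingerprints and feature subsampling
  is the standard choice there (it also decorrelates trees).
* **Histogram gradient boosting** uses `max_bins=2` on binary fingerprints
  — two bins encode a 0/1 feature exactly, so this is lossless and removes
  pure overhead — and `max_bins=64` on continuous embeddings.
* **MLP** uses a single 64-unit hidden layer with early stopping, sized to
  the few-hundred-sample training folds it sees; the library default
  (100 units, no early stopping, 200 full epochs) spends most of its time
  overfitting noise at this scale.

Continuous (embedding) features are standardized inside each training fold
via an in-pipeline `StandardScaler`; binary fingerprints pass through
unscaled. Stochastic families receive a fixed `random_state`.

A practical observation that the test suite exercises: default-alpha ridge
on 1536 standardized embedding dimensions with ~100 training rows sits in
the interpolation regime and recovers even a strongly informative single
coordinate unreliably, while tree-based families find it easily. This is a
property of the estimators, not a bug, and is why the benchmark covers
seven families rather than one.

## 5. Stacked ensemble (`pgccscreen.ensemble`)

The best structure-based and best description-based configurations (by
median round score) are combined by ordinary least squares:
`y ≈ β0 + β1·p_structure + β2·p_description`, fitted with statsmodels so
standard errors and p-values come with the coefficients. Leakage is
avoided by nesting: within each round, the meta-learner scoring a fold is
fitted only on the other folds' out-of-fold base predictions. The ensemble
is compared to each base with a one-tailed paired t-test over round
scores (pairing justified by the shared fold plan). Degenerate fits are
refused for n ≤ 3 (three parameters leave no residual degrees of freedom)
and near-collinear base predictions (|r| > 0.999) raise a warning since
the individual coefficients are then unidentifiable. The deployment model
refits both bases on all data and fits the meta-learner on round-averaged
out-of-fold predictions.

## 6. Virtual screening (`pgccscreen.vscreen`)

An external library is scored by the deployed ensemble and ranked by
ascending predicted `y` (most negative = strongest predicted PGCC
reduction), with a stable mergesort tie-break on compound id. Compounds
already in the training library are excluded by canonical-SMILES identity
(id as fallback); unparsable or description-less compounds are excluded
and audited. `select_top` returns the first k.

## 7. Synthetic fixtures (`pgccscreen.fixtures`)

**Plate images**: anti-aliased flat-top disks on uniform background with
Gaussian noise. Non-PGCC nuclear radii are drawn from 6–9 px; PGCC radii
are 2× (4× area), comfortably separated from the non-PGCC range; nuclei
are placed without overlap (a margin of 4 px) and placement failure raises
rather than silently crowding. Live cells get a calcein disk at 1.5× the
nuclear radius; dead cells get an ethidium-stained nucleus and no
calcein. The generator emulates: size-based PGCC identification, live/dead
channel logic, touching-object separation at moderate density, and shot
noise. It does **not** emulate: uneven illumination, debris and imaging
artefacts, apoptotic fragmentation, overlapping/confluent growth,
out-of-focus planes, or real staining variability — so segmentation
accuracy here is an upper bound, not a field estimate.

**Compounds**: SMILES are assembled from a 22-fragment grammar whose
fragments chain safely (each fragment's terminal atoms tolerate one
additional single bond); every generated molecule is RDKit-validated. The
planted SAR is linear in a random sparse subset of MACCS bits
(`y = intercept + w·fp + N(0, noise_sd)`), which makes recovery testable:
a linear model on the signal-carrying fingerprint must approach ρ = 1 as
noise → 0, and must approach ρ = 0 under a permuted response. A linear
SAR on fingerprint bits is a deliberate simplification — real SARs have
interactions and activity cliffs — so absolute benchmark scores on
fixtures say nothing about prospective chemistry.

**Embeddings**: deterministic hash-seeded Gaussian vectors per text, with
an optional planted signal added to the first coordinate. This captures
the two properties the pipeline relies on (determinism per text, an
information channel orthogonal to structure) and nothing else about real
text-embedding geometry.

## 8. Numerical and statistical choices

* Pearson correlation is computed by `scipy.stats.pearsonr`; constant
  vectors return NaN with a warning instead of a silent 0 or crash.
* The CV plan is an integer assignment array hashed with SHA-256; every
  result records the plan hash so cross-config pairing is verifiable.
* All randomness flows from explicit seeds through `numpy.random.default_rng`;
  reruns of any stage with the same config are byte-identical.
* Fold sizes differ by at most one (`divmod`-balanced partition).
* The paired t-test is one-tailed (alternative: ensemble > base); with few
  rounds its p-values are coarse and should be read as descriptive.

## 9. Limitations

* PGCC calling is purely size-based; ploidy, multinucleation and
  morphology are out of scope.
* The PubChem fingerprint is a dialect (see §3) and must not be compared
  bit-for-bit against server-generated fingerprints.
* Benchmark scores on planted-SAR fixtures are internal quality checks,
  not estimates of prospective screening performance.
* Hyperparameters are fixed, not tuned per dataset; the grid compares
  families under a common, compute-bounded footing rather than finding any
  family's optimum.
* The paired t-test across CV rounds treats rounds as independent
  replicates, which repeated CV only approximates.
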