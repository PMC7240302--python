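# Methods

This note documents the models, conventions and parameter choices behind
the package, what the synthetic-data generator does and does not emulate,
and the numerical decisions a user should know before trusting a result.

## Dendrite-orientation histograms

A neuron's dendrite orientation is summarised by the angular distribution
of vectors from the dendrite's **first branching point** to every
contributing element — each suprathreshold pixel of a 2-D image (3-D
stacks are reduced by maximal z-projection first), or each dendrite point
of an SWC skeleton. Angles are measured in degrees counterclockwise from
the +x axis (for images, +x is the column axis and +y points towards
smaller row indices), binned into 12 half-open 30° bins `[30k, 30(k+1))`,
and bin counts are divided by the total vector count, so an unscaled
histogram sums to 1 (enforced to 1e-9). Conventions the underlying
measurement protocol leaves open are fixed as follows:

* pixels exactly at the reference point contribute no vector;
* the image intensity threshold defaults to Otsu's method — a reproducible
  stand-in for a per-image manual choice; an absolute threshold can be
  passed instead, and `threshold_sweep` exposes the sensitivity of the
  histogram to this choice as data rather than a guess;
* a zero-suprathreshold image raises `NoForegroundError`, distinct from a
  valid histogram with zero mass in some bins.

For cross-stage size visualisation, an early-stage histogram can be
rescaled by the ratio of vector counts (`scale_histogram`); scaled
histograms are display artifacts and are rejected by the similarity index.
Averages over histograms report per-bin mean ± s.e.m. (sample sd / √n);
n = 1 yields s.e.m. 0 with an explicit single-sample flag rather than NaN.

## Similarity index and nearest-reference classification

Two normalised histograms are compared by `Σ_k |h_k − g_k|` — an L1
distance bounded by 2, symmetric, zero iff equal, satisfying the triangle
inequality. Classification assigns a query to the subtype whose reference
histogram (the per-subtype mean of a control population) minimises this
index. Exact ties break deterministically towards the earlier subtype in
a < b < c < d order and are flagged; they occur only on constructed inputs.
The classifier is exposed in scikit-learn estimator form
(`DendriteOrientationClassifier.fit/predict`), so it composes with sklearn
model selection; `classify_by_dendrite` is the single-query wrapper, which
additionally requires references for all four subtypes.

Whether the index should be computed on per-neuron histograms or smoothed
averages is not dictated by the method itself; the functions operate on
whatever normalised histograms they are given, and the pipeline compares
per-neuron queries against per-subtype reference averages.

## Axon position in the lobula plate

The axon reference point (the terminal in the simulator; any designated
node in general, with the convention recorded in metadata) is normalised
against the lobula-plate frame: 0 at the posterior edge, 1 at the anterior
edge, evaluated at the reference point's proximodistal position with
linear interpolation between tabulated edge rows. Positions beyond an edge
are clamped to [0, 1] and flagged. The quantity is invariant under joint
translation and scaling of frame and point.

Positions are grouped into four layers by 1-D k-means with deterministic
initialisation at the (2i−1)/2k data quantiles (no seed dependence;
delegated to scikit-learn with `n_init=1`), clusters relabelled in
ascending positional order, and boundaries taken as midpoints between
adjacent cluster means. A position exactly on a boundary assigns to the
lower group — an arbitrary but fixed tie rule. Layers map to subtypes via
the fixed table 1↔a, 2↔b, 3↔c, 4↔d. Whether layer 1 sits at normalised 0
or 1 cannot be fixed from text descriptions of the anatomy, so the
direction is a `layer_order` parameter (`posterior_first` default,
`anterior_first` available); the default is a configuration choice, not an
anatomical claim.

## The transcription-factor code

Subtype identity is a three-bit code: a Dac/Ab-class flag, a mutually
exclusive Omb/Pros-class flag (exactly one class flag is set; the classes
repress each other), and a Grain flag marking subtypes b and c. Grain
overexpression sets the Grain bit, knockdown clears it, and class flags
never change — hence the gain image is {b, c}, the loss image is {a, d},
and gain∘loss / loss∘gain restrict to identities on those images. When
codes are not supplied directly they are derived from cluster mean
expression by the same midpoint rule used for identity assignment.

## Expression analyses

**QC.** Cells need ≥ 200 total counts and ≤ 10% mitochondrial-like and
≤ 10% heat-shock-like counts (category flags from `var`, falling back to
`mt:`/`Hsp` name prefixes); genes must be detected (count > 0) in ≥ 3
cells. Cells are filtered before genes, both recomputed on the surviving
submatrix; because removing a gene can in principle push a borderline cell
back under the UMI floor, the two passes are iterated to a fixpoint so that
the output is guaranteed violation-free and the filter is idempotent. The
removal report lists every entity with its reason and round.

**Normalisation** is per-cell depth scaling to 10,000 counts followed by
log1p (delegated to scanpy), recorded in `uns`. The depth-scaled layer, not
the log layer, feeds fold-change computation.

**Differential expression** is a threshold filter, not a significance
test: gene g passes for cluster A over B iff detection fraction
`f_A ≥ 0.5`, `f_A − f_B ≥ 0.5`, and `(m_A + ε)/(m_B + ε) ≥ 2` with
pseudocount ε = 0.01 on depth-normalised means. The twofold requirement is
interpreted on the linear normalised-mean scale; threshold, ε and the
detection count floor are configurable. With a fraction-difference
threshold ≥ 0.5 the filter is antisymmetric in direction. Per-stage DEG
sets combine into any-stage (union) and all-stage (intersection) sets with
a per-gene stage profile.

**Cluster identity.** Eight clusters are mapped onto (T4|T5) × (a–d) by
successive midpoint splits: the type marker separates the four T4 from the
four T5 clusters (threshold = midpoint of the two groupwise means; any
overlap raises an error naming the marker), the a,b marker splits each
type (cross-checked against the c,d marker), and the b,c marker resolves
b vs a and c vs d. The result is a complete bijection or an error — there
is no silent partial assignment.

**Dynamics categories.** Given per-stage marked subtype sets (per type)
and a type-level flag, a differential gene is labelled `type_specific`
(differential only between T4 and T5 as groups, or subtype-specific in
only one type), `late_only` (subtype-differential exclusively at ≥ 60 h),
`switching` (the marked set changes between differential stages), or
`stable_subtype_specific` (constant set spanning ≥ 2 consecutive stages).
A gene differential at exactly one pre-60 h stage fits none of the
definitions cleanly; such transient patterns are labelled `switching`,
the category for discontinuous patterns. Stages 36–72 h are required.

**Grain score.** Per optic lobe, each subtype's mean cell-body intensity
is divided by the mean of that lobe's Lim1-negative background cell bodies
(≥ 10 required). Subtypes are read from the markers themselves (Lim1 for
T4/T5, Dac for a,b, the b,c reporter for b,c), never from ground-truth
columns, and the score is invariant to global intensity rescaling.

## The synthetic-data generator

The generator produces the statistical structure the analyses assume,
with ground truth for every label, and nothing more:

* **Branch directions** are von Mises around a per-subtype generating
  angle (defaults a = 0°, b = 180°, c = 90°, d = 270° — only the relative
  geometry, opposite pairs 90° apart, matters) with concentration κ
  (default 3; κ = 0 uniform, κ = ∞ degenerate). At κ = 3 and 200 branches
  the circular mean lies within ±10° of the generating angle in ≥ 99% of
  seeds.
* **Arbor size** follows a piecewise-linear stage profile (relative sizes
  0.15/0.30/0.55/0.80/1.00/0.75 at 24/36/48/60/72 h APF/adult): monotone
  growth to a 72 h maximum, then pruning. Branch counts scale with the
  profile from a 240-branch maximum; cable volume follows.
* **Axon positions** are Normal(center, 0.03) on the normalised axis with
  layer centers (0.2, 0.4, 0.6, 0.8) inside a rectangular plate frame.
* **Clones**: four neurons (2 T4 + 2 T5) per neuroblast clone share a
  retinotopic position and carry subtype pairs {a,b} or {c,d}.
* **Counts** are negative binomial (mean 10 for an "on" marker, dispersion
  5, on/off fold 50) over a ~25-gene panel implementing the marker
  program: a T4 type marker, a,b / c,d / b,c pair markers, one
  single-subtype marker, late-only genes (differential only ≥ 60 h),
  switching genes (pattern {a,b}→{c,d} or {b,c}→{a,d} with a
  non-differential transition stage, so they drop out of the all-stage
  set), housekeeping, mitochondrial-like, heat-shock-like and one
  near-absent gene. Engineered QC failures (low-count and stressed cells)
  are injected per stage with their failure mode recorded.
* **Cell bodies**: b,c intensities are 3× the lobe's background level by
  default, with 8% multiplicative noise; a,d and Lim1⁻ cells share the
  background distribution.

Determinism: every generator derives child generators from one integer
seed; identical seeds give byte-identical outputs (including rasterised
images). Outputs are text formats only: SWC (1-based ids, 2 = axon,
3 = dendrite, designated reference nodes in comment headers), 16-bit
TIFF/PNG, CSV tables, MatrixMarket counts with gene/cell sidecars, YAML
parameter echoes.

Not emulated — and therefore not validated by passing tests: optics/PSF
and 3-D image stacks, realistic transcriptome breadth, ambient RNA and
doublets, batch effects and sex-driven expression variation, biological
variability in arbor topology (branches are straight radial segments),
and any developmental dynamics of layer formation. Passing tests show the
*procedures* are correct under the stated statistical assumptions, not
that real imaging or sequencing data satisfy those assumptions.

## Experiment design and problem sizes

The pipeline's wildtype run simulates 4 neurons per subtype per cell type
per stage across all six stages (192 neurons) and classifies each neuron
against per-stage subtype reference averages and pooled axon-position
boundaries. Perturbation experiments apply the code change *before*
morphogenesis — identity conversion, the mechanism the anatomical evidence
supports — and classify perturbed neurons against references and
boundaries from an unperturbed control population with a derived seed; an
optional `conversion_penetrance` (default 1.0) models partial conversion.
Perturbation analyses run on adult-stage populations (32 neurons, 8
clones), matching the stage at which mosaic phenotypes are scored. The
orientation-recovery benchmark uses 64 neurons (16 per subtype, ≥ 200
branch points) plus an 800-neuron κ = 0 control, where accuracy sits at
chance (25% ± 5%). The expression run uses 60 cells per cluster per stage
(~2430 cells per stage including engineered failures) — small enough for
seconds-scale runs, large enough that the detection-fraction thresholds
are crossed with wide margins.

## Known limitations

* The absolute subtype angles and the layer-numbering direction are
  configuration conventions; only relative geometry is meaningful.
* The DEG filter's "twofold" is on linear normalised means; analyses tuned
  to a log-scale fold definition will differ near the threshold.
* The dynamics categoriser assumes shared T4/T5 subtype patterns when
  given plain sets; genuinely divergent per-type patterns should be passed
  as explicit `StageStatus` values.
* The axon clusterer assumes four occupied layers; populations confined to
  two layers (e.g. fully penetrant perturbations) must be classified with
  boundaries from a control population, as the pipeline does.
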