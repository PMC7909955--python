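# Methods

This note documents the models, statistics and numerical choices behind
`mbcs`, what the synthetic generator does and does not emulate, and the
design decisions taken where more than one reasonable construction exists.

## Data model

A connectome is a neuron table (`neuron_id`, `super_class` ∈ {PN, KC, MBON,
DAN, other}, `cell_type`, optional `subtype`, sensory `modality`,
`glomerulus` for PNs, and dendritic/axonal compartment sets drawn from the
15 lobe compartments plus calyx regions), a weighted edge list (`pre_id`,
`post_id`, integer synapse count, optional postsynaptic site class
dendrite/axon/unknown), and an optional synapse-site table with 3D positions
in micrometres. Validation enforces unique neuron ids, resolvable edge
endpoints, non-negative weights, at most one edge per (pre, post, site
class), and finite synapse coordinates; synapse rows without a matching edge
are kept but logged.

`ConnectivityMatrix` is a labelled dense matrix tagged with its scale:
raw `counts`; `input_fractions` (each column divided by its sum, so every
column sums to 1 or is exactly 0 for an isolated target — zero columns are
retained to preserve shapes for downstream products, and logged);
`binary` (counts ≥ t, inclusive threshold, t = 5 by default for PN→KC
matrices); `effective` (products of input-fraction matrices, column sums
≤ 1); and `row_fractions` (modality tables whose rows sum to 1).

**Effective connectivity.** For source→intermediate fractions A and
intermediate→target fractions B, the effective source→target influence is
(AB)ᵢⱼ = Σₖ AᵢₖBₖⱼ — the fraction of j's input attributable to i through
one intermediate, under the assumption that an output synapse conveys each
of its owner's inputs in proportion to their synapse counts. Only two-step
paths are computed by default; deeper chains can be formed by repeated
multiplication but are deliberately not wired into any analysis.

**Modality fractions and KC groups.** Per KC (or KC type), sensory input
fractions are synapse-count shares of annotated PN modalities; per MBON they
are computed on the effective PN→MBON matrix and divided by the MBON's total
sensory input. A KC joins the `olfactory_thermo_hygro` or `olfactory_visual`
stream when its dominant non-olfactory fraction reaches a configurable
threshold (default 0.25, thermo/hygro winning ties), otherwise it is
`olfactory`. The threshold is deliberately low: non-olfactory streams are
minorities of the KC population and their members still receive olfactory
input.

**Feedback motifs.** A DAN is classified `self` when every MBON providing at
least the threshold number of synapses (default 5) has dendritic
compartments intersecting the DAN's axonal compartments, `cross` when none
does, `both` for a mixture, `neither` without MBON input. Synapses onto DAN
axons are excluded by default (`dendrite_only=True`); edges without a
site-class annotation count as dendritic, since compartment membership, not
site class, carries the definition. A DAN without axonal compartment
annotation is an error rather than a silent `neither`.

**Root-distance ECDFs.** Synapse positions are snapped to the nearest
skeleton node (Euclidean); the geodesic along-tree distance from the SWC
root is divided by the maximum root distance over dendrite-class nodes
(all nodes when the skeleton carries no class labels), giving the 0–1 axis.
The reference curve's median — the normalised distance at which half of the
reference (KC) synapses have occurred — is returned as the comparison line.
Degenerate inputs (empty synapse sets, single-node or zero-extent skeletons)
are errors.

## Null models

**Degree-preserving PN→KC shuffle.** Each row (KC) of the binary matrix
keeps its exact degree and redraws its partners without replacement with
probability proportional to the original column sums. This retains the KC
claw-count distribution and each uPN's average connection probability but no
other structure. Sampling without replacement keeps the matrix binary (a KC
cannot claw the same uPN twice in the binary representation); a consequence
worth knowing is that marginal inclusion probabilities are exactly
proportional to the weights only in the low-degree regime — successive
weighted sampling slightly flattens extreme weights when row degrees
approach the number of columns.

**PCA envelopes.** Variance fractions are eigenvalues of the column-centred
covariance with KCs as observations and uPNs as variables (the transpose is
available via `center="rows"`), normalised to sum to 1 and sorted. Per
component, the envelope is the central 95% percentile band over shuffles;
`flags_above` (observed above the upper bound) is the structure detector,
while `flags_outside` (either side) is the quantity whose null rate is the
nominal 5% and is what the calibration tests measure. For calibration the
observed matrix must be exchangeable with the envelope draws, so the
`observed=` argument lets callers compare one extra shuffle of the same base
matrix against the envelope; an independent null-generator draw tested
against shuffles of itself is only approximately calibrated because the
shuffle conditions on realised column sums.

**Convergence null.** Observed convergence counts, per downstream neuron,
the number of distinct MBON cell types supplying at least 10 synapses. The
null conserves each MBON cell's total output synapse count and reassigns it
multinomially over candidate targets (all non-MBON neurons with any input)
with probabilities proportional to their total input synapse counts —
resampling at the synapse level, which is the natural reading of weighting
by input synapse totals.

**Nearest-neighbour subtype test.** Each calyx synapse is matched to the
nearest synapse of a *different* neuron; the statistic is the fraction of
same-subtype matches. The permutation null relabels *neurons*, not
synapses — the synapses of one neuron are not exchangeable units — and the
p-value uses the add-one estimator (1 + #{null ≥ observed})/(1 + n_perm),
which can never be exactly zero.

## Calyx spatial statistics

Boutons are detected per PN by single-linkage agglomeration of synapse sites
cut at a link distance of 2.5 µm (configurable; the algorithm and distance
are a package choice — boutons are compact relative to inter-bouton spacing,
and single linkage is deterministic). The bouton centroid is the mean of its
member sites.

The radius shuffle reassigns every claw uniformly among boutons whose
centroids lie within r of the claw's own bouton centroid (itself included),
preserving per-KC claw counts; r = 0 is the identity, so structure at scales
above r survives while structure below r is randomised.

Participation ratio: PR(w) = (Σw)²/Σw² on the per-glomerulus column-sum
vector of the PN→KC weight matrix (the covariance-eigenvalue variant is the
`kc_dimension` spectrum statistic; the marginal-vector reading is the
default because the quantity is described as uniformity of glomerulus
representation). Bounds 1 ≤ PR ≤ N with equality at one-hot and uniform
vectors.

Dimension of the KC representation: random PN patterns (i.i.d. standard
normal by default; Bernoulli available) drive KCs through the weight matrix;
a single global threshold is set at the (1 − f) quantile of all drives so a
fraction f = 0.05 of KCs is active per pattern on average; the dimension is
the participation ratio of the eigenvalues of the binary activity covariance
estimated over patterns (computed via SVD of the centred activity). This
quantity controls how well a linear readout can separate random input
ensembles; it is invariant to KC permutation and overall weight rescaling,
and grows toward the PN count for the linear identity model.

The fibre-turnover statistic takes per-neuron positions sampled on a common
arc-length grid and reports, per step, the fraction of the k = 10 nearest
other fibres (same step index) that differ from the previous step.

## Similarity and clustering

Cosine similarity is computed on partner profiles after dropping excluded
partner columns (e.g. MB-intrinsic inputs when comparing DANs); zero
profiles get similarity 0 everywhere by convention, with a warning.
Spectral clustering runs on the negatives-clipped similarity as a
precomputed affinity; when k is not given it is chosen by the best
silhouette score on the distance 1 − cosine over k = 2..10. All-identical
profiles return k = 1 with a warning. Hierarchical clustering stores the
full dendrogram (average linkage for morphology-distance matrices, Ward on
Manhattan distances between per-neuron input-fraction profiles for upstream
connectivity), with cuts by height or by cluster count.

The Mantel statistic is the Pearson correlation of the upper-triangle
vectors; permutations act jointly on rows and columns of the second matrix,
all n! permutations are enumerated when that is no more work than the
requested n_perm (guaranteeing exactness for n ≤ 8 at the default 10⁵), and
p = (1 + #{r_perm > r_obs})/(1 + #perms) with a strict "higher than" count.
The compartment-level input/output similarity correlation applies the same
permutation scheme to compartment labels of one similarity matrix. Pooling
to type level averages cell pairs across types (excluding self-pairs within
a type), after the cell-level cosine computation.

## Synthetic connectome generator

The generator emulates, at ~10% scale, the statistical structure the
analyses assume. 51 olfactory glomeruli plus 4 thermo/hygrosensory and 6
visual channels each get 2–4 PNs; each PN makes ~6 boutons (Normal(6, 2),
min 1) placed at its channel's centre (uniform in a 25 µm-radius model
calyx) plus 5 µm Gaussian jitter, so same-glomerulus boutons are closer
than different-glomerulus ones. 200 KCs are drawn from the observed
14-subtype census proportions (590:99:8:4 γ subtypes, 91:127:119 α′/β′,
60:223:354:252 α/β out of 1927); claw counts are 1 + Poisson(mean − 1) with
mean 5.6 (a shifted Poisson — only the mean is empirically constrained, so
the simplest single-parameter family with support ≥ 1 is used; zero
dispersion gives the deterministic rounded mean). Each claw draws a source
modality from its type's mixture (γd and α/βp ~90% visual; γt, γs and
α′/β′ap1 lean thermo/hygro; all others olfactory), then a bouton of that
modality with probability ∝ (per-type glomerulus factor) ×
exp(−distance/locality_scale). With `glomerular_bias = 0` and
`locality_scale = ∞` every admissible bouton is equally likely, which *is*
the popularity-proportional random sampling null; positive bias multiplies
channels by i.i.d. log-normal per-(type, channel) factors of that log-scale,
and a finite locality scale concentrates a KC's claws around its anchor.
Synapses per claw are 5 + Poisson(3), so default edge weights clear the
5-synapse binarisation threshold by construction. One MBON per lobe
compartment samples KCs whose axons cross it (p = 0.3, weights 5 +
Poisson(5)); MBON outputs go to 40 downstream neurons with a hub bias that
plants above-null convergence; 12 DANs in 3 subtypes receive block-
structured input from a 30-neuron upstream pool (within-block weights
10 + Poisson(5), 10% weak cross-block noise) plus stochastic same- and
cross-compartment MBON feedback. Ground truth (KC group labels, claw→bouton
map, per-type channel factors, DAN subtypes) is emitted alongside.

What the generator does **not** emulate: real neuron morphologies (skeletons
for ECDF tests are simple synthetic trees), inhibitory feedback (APL/DPM),
KC→KC synapses, multi-compartment DAN axons, synapse-count overdispersion,
or hemibrain-scale numbers (a full-scale run is just a config change but is
not the tested default). Passing tests therefore demonstrate correctness of
the statistics and power against the planted structure classes, not fidelity
to any particular real dataset.

## Modality-segregation learning model

Stimuli are pairs of random binary patterns (density 0.5, 50 PNs per
modality), built as **all combinations** of per-modality component pools —
20 olfactory × 10 visual = 200 stimuli for the factorizable task and
5 × 5 = 25 for the unfactorizable one. This construction keeps the two
tasks comparable in difficulty and makes "unfactorizable" precise: the
pair label is drawn i.i.d. per combination and is therefore not a function
of the components separately. In the factorizable task each component
carries a subvalence (+1 positive, −1 neutral — two classes are needed for
a discriminative fit) and the net valence combines them by OR (positive if
either component is positive) by default; AND is available because both
conventions appear in descriptions of this task, and for balanced ±
subvalences the two are label flips of each other. Degenerate single-class
draws are resampled a bounded number of times.

KCs sample 6 distinct PNs uniformly from their allowed pool — both
modalities (`shared`) or one modality per half of the population
(`separate`) — with unit weights. Activity is binary with one global
threshold; because drives are small integers, ties at the threshold are
broken at random (seeded) so that exactly a fraction f of all
(KC, stimulus) activations occur. The default coding level is f = 0.10:
at the default n_kc = 100 this leaves ~10 active KCs per stimulus, enough
for the component dichotomies to be linearly decodable; at f = 0.05 the
code itself (2–3 active KCs per modality block) becomes the bottleneck and
architecture differences are masked.

The readout is a ridge-regularised least-squares fit (α = 10⁻³, unpenalised
intercept) of ±1 targets, thresholded at 0 with ties resolved positive.
With a **shared reward signal** a single fit sees the net valence. With
**separate reward signals** each modality's KC block is fit only against
that modality's subvalence — modelling reinforcement that modulates only
matching KC→MBON synapses — and the two readouts converge additively;
the scalar output threshold of the converged unit is then set on the net
valence (a deterministic one-dimensional decision on the summed score,
folded into the intercept). The threshold step is necessary and minimal:
summed ±1-scale scores place mixed-subvalence stimuli near zero, where a
fixed zero threshold is a coin flip, while the per-modality plasticity
itself never sees the net valence. Separate reward mode requires the
separate architecture and a factorizable task (there are no per-modality
targets otherwise); both misuses raise errors pointing to shared mode.

Reported performance is training-set accuracy over the presented stimuli
(the task is discrimination of the experienced stimulus set, not
generalisation; a held-out evaluation is a one-line change through
`evaluate`). Experiments run 20 fresh draws of stimuli and wiring per
condition and report mean ± SEM.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator` objects or explicit
seeds; the CLI expands one global seed into independent per-stage child
seeds via SHA-256 so stages are individually reproducible, and `mbcs run`
writes a manifest with the config hash and library versions. Input-fraction
columns are checked to 10⁻¹², eigenvalues are floored at 0 before
participation ratios, cosine matrices are symmetrised and clipped to
[−1, 1], and Mantel's strict ">" uses a 10⁻¹² guard against floating-point
ties. Matrix and table writers are byte-stable given fixed input order.

Test and verification problem sizes (e.g. 60–200 KC generators, 150-shuffle
envelopes, 100 calibration replicates, 400-pattern dimension estimates) were
chosen so the full suite exercises every pipeline at statistically
meaningful power while remaining a desk-scale computation; all sizes are
parameters, and full-scale runs only require larger configs.

## Known limitations

* The degree-preserving shuffle's inclusion probabilities deviate from exact
  weight proportionality at high row degree (see above); the analyses here
  operate at claw counts ≪ number of uPNs where the effect is negligible.
* Spectral clustering inherits scikit-learn's k-means assignment step;
  labels are deterministic only through the seed, and silhouette selection
  can be unstable for barely separated groups.
* The dimension model assumes i.i.d. PN activity; correlated odor ensembles
  would need a supplied pattern distribution.
* `pool_by_type` averages pairwise cell similarities ("pool after"); pooling
  synapse counts before the cosine ("pool before") is a different estimator
  that can be built from `to_matrix` output directly.
* The effective-connectivity construction treats synapse counts as linear
  influence proxies and ignores transmitter sign and dynamics.
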