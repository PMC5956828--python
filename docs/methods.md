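# Methods

## Model and procedure

`embedclass` turns per-tile deep feature vectors into graded slide-level
verdicts. The pipeline has five stages.

**Lesional gating.** Each tile carries a lesional probability — in the
two-model design this is the grouped-lesion head's output; the mock
provider defines it as the summed probability mass of the five tumor
classes. Tiles are kept iff `p_lesional > lesional_threshold` (strict
inequality at the default 0.85). If fewer than `min_lesional_tiles`
(default 15) survive, the slide is not classified: the verdict is
`INSUFFICIENT_LESIONAL` and the five highest-scoring lesional tiles are
carried along for manual review. Otherwise at most `max_tiles_per_slide`
(default 100) tiles are sampled uniformly without replacement,
seed-determined. The boundary is inclusive: exactly 15 tiles proceed.
A low-threshold variant (minimum 5) is a one-parameter change.

**Reference map.** A labeled sample of training-tile features is embedded
in 2-D, by t-SNE (perplexity 30, PCA initialization, 500 gradient
iterations, fixed seed, single-threaded — fully deterministic given the
seed) or by projection onto the top two principal components (PCA mode,
deterministic with no seed). The map is refined in a single pass: every
point's own-class fraction among its `n_check_neighbors` nearest map
neighbors (default 300, Euclidean on the plane, self excluded) is
computed, and points below `own_class_min` (default 0.5, a majority-vote
reading of "deviates from its cluster") are dropped. Refinement that would
empty a class raises rather than silently losing a class. The neighbor
window must stay below the per-class tile count for the fraction to be
meaningful: 300 suits 350–600 tiles/class; desk-scale maps at 60/class
use 50. A single pass is used; on well-separated maps the operation is
empirically idempotent, which the suite asserts.

**Joint re-embedding.** Each slide's sampled tiles are embedded *with*
the reference from scratch (same t-SNE parameters and seed). Coordinates
are therefore not comparable across slides, but the cluster structure is
preserved — the suite checks that per-class reference purity moves by at
most 0.05 when ≤ 100 queries are added. PCA mode projects queries onto
the reference-fitted components instead, which is exact.

**Tile discretization.** A query tile's k = 25 nearest *reference* points
(queries never vote; distance ties broken by reference order via a stable
sort) are examined. If the modal class holds ≥ `knn_purity` (0.85, i.e.
≥ 22 of 25 — the ≥/> choice at exact equality is ≥) the tile is
discretized to that class; otherwise it is an OUTLIER. On top of the
purity rule the pipeline applies an *unoccupied-space guard*: a radius is
computed from the reference map alone — `outlier_distance_factor` (3.0) ×
the 95th percentile of the reference points' own k-th-neighbor distance —
and any query whose k-th reference neighbor lies beyond it is an OUTLIER
regardless of purity. The guard operationalizes "tiles localizing to
undefined/unoccupied space": without it, a novel cluster floating in
empty map space can still have a *pure* (single-class) set of nearest
reference points, namely the edge of whichever cluster happens to be
closest, and would be confidently miscalled. Because the radius is
derived from the reference before any query is seen, it involves no
post-hoc tuning; setting the factor to `None` recovers the pure purity
rule (which is also the form the brute-force kNN oracle checks).

**Verdict.** The calls form a contingency table (zero classes omitted).
`chi2_uniform` computes Σ(Oᵢ−E)²/E with E = n/k against an equal split,
df = k−1, p from the χ² survival function; a single category returns
(0, 0, p = 1) by convention. No continuity correction and no
minimum-expected-count guard — the procedure is deliberately the plain
statistic on small (15–100 tile) tables. `decide` then:

1. *Outlier check* — χ² over all present categories including OUTLIER;
   if p < α **and** OUTLIER is a modal category → `UNDEFINED`. The modal
   requirement keeps a significant table that is dominated by a real
   class (with a minority of outliers) on the diagnostic path.
2. OUTLIER is set aside; no real classes left → `UNDEFINED`.
3. *Iterative elimination* — a singleton is a `DIAGNOSIS`; otherwise
   test against uniform; p ≥ α stops with a `DIFFERENTIAL` (classes
   sorted by count, descending, ties by label); else the smallest class
   (ties by label order) is removed and the loop repeats. Each
   elimination strictly shrinks the set, so the procedure halts in ≤ k
   iterations.

α defaults to 0.01 and is fixed a priori; lowering it only ever enlarges
the retained class set (asserted as a property). The full trail —
remaining classes, counts, statistic, df, p, removed class per
iteration — is serialized with the verdict.

**Composite classifiers.** The probability baseline is the arithmetic
mean softmax vector over the gated, sampled tiles (argmax ties resolved
by class order). The combined call returns the shared class iff the
map-based verdict is a DIAGNOSIS of the baseline's top class, else
`UNDEFINED`. The hybrid score is `w·frac + (1−w)·meanprob` with w = 0.5
by default (the blend weight is not canonical; it is exposed in the
config). Tile fractions are computed over class-called tiles only —
OUTLIER is excluded from numerator and denominator, so a differential can
never contain "undefined" and an all-outlier slide has a zero fraction
vector.

## Evaluation

mROC is approximated as the macro average of one-vs-rest AUCs, class c's
own score column as discriminant, midrank tie handling (the suite checks
exact agreement with a Mann–Whitney pair-counting oracle). Classes absent
from the truth set are skipped; DIFFERENTIAL/UNDEFINED/INSUFFICIENT
slides are excluded from accuracy, matching the workflow's reading of
abstention. Cutoff sweeps use one uniform rule — a slide is classified
iff its confidence score reaches the cutoff — where the probability
mode's score is the top mean probability and the map mode's score is the
fraction of tiles in defined (non-outlier) space; coverage is therefore
non-increasing in the cutoff in both modes. The error taxonomy assigns
TYPE_A when a non-lesional truth is called a lesion class, TYPE_C
whenever the truth class was never trained, and TYPE_B to the remaining
misclassifications among trained classes (canonically tumor-for-tumor;
the rarer lesional-truth-called-non-lesional case is folded in here so
that CORRECT + A + B + C + EXCLUDED always partitions the cohort).

## Synthetic study conditions

The fixture generator emulates the statistical structure the workflow
assumes, not histology itself. Class clusters are isotropic Gaussians in
a `feature_dim = 64` space (the true hidden-layer width of a
fine-tuned network is not canonical; the dimension is configurable and
64 keeps desk-scale runs fast). Means are placed by seeded random draws
with rejection until all pairwise distances reach
`class_separation × within_class_sd` (default 10 sd — clusters a
well-trained network separates cleanly); impossible geometries (e.g. too
many classes in 1-D) raise a placement error. Reference sets draw
350–600 tiles per class by default; tests and the acceptance script use
60/class so that ~70 joint t-SNE runs fit in minutes. Mock class
probabilities are the softmax of −d²/T against the class means, so a
tile at its mean scores ≈ 1 and an equidistant tile scores uniformly;
the lesional probability is the summed tumor-class mass. Slides mix
lesional tiles from one tumor cluster with background tiles from
non-lesional clusters. Novel slides draw from a cluster ≥ `offset_sd`
(10) from every trained mean, and by default the placement requires the
*nearest* trained mean to be a tumor class so the novel lesion passes
the lesional gate — the open-set scenario of interest; a novel cluster
nearest to normal tissue would be gated out upstream as
`INSUFFICIENT_LESIONAL` before the map ever sees it.

What passing tests on these fixtures show: the decision machinery, the
discretization geometry and the open-set behavior are correct under the
stated cluster assumptions. What they do not show: performance on real
H&E tiles, where class clusters are anisotropic, overlapping and
multi-modal, stain and scanner variation shift features, and lesional
probabilities are imperfectly calibrated. Cohort-level accuracy numbers
from real slide sets are out of scope here.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; t-SNE uses a fixed `random_state` and one thread, making the
  classify output byte-identical across runs.
- Distance ties at the k-th neighbor: stable argsort, i.e. reference
  (tile-id) order. Modal-class and smallest-class ties: label order.
  Probability argmax ties: class order.
- Probability vectors must sum to 1 within 1e-6 (drift renormalized,
  worse rejected with the offending tile id); lesional probabilities are
  clipped against 1-ulp overshoot.
- Partial edge tiles are dropped, not padded (fixed-size classifier
  input); tile coordinates are 0-based with half-open pixel bounds in
  row-major order so CAM reassembly is reproducible.
- Images smaller than one tile yield an empty tiling plus a warning
  rather than an error.

## Known limitations

- The unoccupied-space radius is a heuristic for "empty map space"; on
  maps whose clusters vary wildly in density the 95th-percentile basis
  may need the factor adjusted.
- Joint re-embedding is O(slides × t-SNE); the projection fast path
  (PCA mode, or nearest-reference placement) trades the from-scratch
  protocol for speed and is not the default.
- The mROC construction is a macro one-vs-rest approximation; other
  multiclass ROC constructions would give different absolute AUCs.
- Refinement is single-pass by design; iterating to a fixed point could
  remove additional borderline points on poorly separated maps.
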