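# Methods

## Random-walker segmentation (`rwct.rw_core`)

The image is a weighted lattice graph: nodes are pixels, edges join
4-connected (optionally 8-connected) neighbours, and the weight of edge
(i, j) is the Gaussian affinity v_ij = exp(−β (t_i − t_j)²), floored at
ε = 1e-10 so the graph stays numerically connected. Intensities are first
rescaled affinely to [0, 1] (disable with `rescale=False`); this makes β
independent of the image's intensity scale — the segmentation is invariant
to any map t → a·t + b with a > 0, which the property tests assert. The
default β = 90 on normalized intensities is a commonly effective setting
for seeded walkers; it is a free parameter of every public entry point.

For each label L the walker probability field is the unique harmonic
function equal to 1 on L's seeds and 0 on all other seeds: with the
Laplacian partitioned into seeded/unseeded blocks, L_uu x = −L_us b is a
sparse symmetric positive-definite system. K − 1 systems are solved and the
last label takes the complement, so per-pixel probabilities sum to exactly
one. Systems up to 1e5 unknowns use a sparse LU factorization with one step
of iterative refinement; larger systems fall back to conjugate gradients at
tolerance 1e-8. Unseeded pixels with no path to any seed are rejected with
a diagnostic listing the disconnected component. The mask is the per-pixel
argmax, ties broken toward the smallest label. Pixels are indexed row-major
(i = row·W + col), coordinates are 0-based (row, col).

Numerical note: with the ε floor active (large β and unit-contrast edges),
the Dirichlet systems have condition numbers up to ~1/ε = 1e10. In double
precision two *different* exact direct methods then legitimately disagree
by more than 1e-8, so the sparse-vs-dense solver agreement tests run at
β = 10 on random images, where no weight approaches the floor and agreement
to 1e-8 is a meaningful correctness check. Large-β behaviour is exercised
separately by the phantom segmentation tests (exact recovery of crisp
boundaries).

## Terminal-graph minimum cut (`rwct.st_cut`)

The hybrid segmenter pipes the walker posteriors into an s-t cut. Each
pixel gets t-links to the source Q and sink I carrying −log of the
opposite-class probability (probabilities clipped to [1e-9, 1−1e-9],
capacities to [0, 1e9]); seeds are hard-linked with capacity 1e9. N-links
carry λ_n · v_ij, λ_n = 1 by default; λ_n trades data fidelity for boundary
smoothness, and at λ_n = 0 the cut provably reduces to the posterior
argmax (tested). The cut is computed exactly by max-flow (networkx
preflow-push); parallel edges accumulate capacity. The reported cut value
is recomputed from the returned partition and must equal the flow value by
duality — an invariant the tests check on every solved instance, alongside
exhaustive 2^n enumeration on instances up to 12 pixels.

A pure-cut mode replaces the walker posterior with a seed-intensity
histogram likelihood (32 bins, add-one smoothing); it is provided for
comparison and inherits no spatial information beyond the n-links, so it is
substantially weaker on low-contrast or noisy inputs.

Multi-label inputs are segmented one-vs-rest in ascending label order; a
pixel claimed by several cuts takes the smallest label and an unclaimed
pixel falls back to the probability argmax. The published formulation
covers only the two-terminal case; the one-vs-rest extension is this
package's design choice, as is the specific coupling of walker posteriors
to t-links (the source text juxtaposes the two formulations without
specifying their composition, and −log-posterior t-links are the standard
way to combine a per-pixel likelihood with a cut).

## Metrics (`rwct.seg_metrics`)

Dice: 2|R1∩R2|/(|R1|+|R2|); both-empty pairs return 1 by convention
(documented, tested). Hausdorff: distances between foreground *pixel
centers*, Euclidean, scaled by the physical spacing; the symmetric value is
the max over both directed max-of-min distances, computed with KD-tree
nearest-neighbour queries and verified exactly against all-pairs
enumeration on small masks. `percentile=95` gives HD95. Empty masks are
rejected with a diagnostic, since the distance is undefined.

## Phantoms (`rwct.phantoms`)

The CT phantom emulates a thorax slice at 80×80 px: soft tissue at
intensity 0.55, two elliptical lung fields at 0.15, and lesions at 0.85 —
disk nodules (radius 4–7 px) plus, by default, an eccentric hollow in the
upper part of the first lung: an annular cavity wall (outer radius 9 px,
wall 3 px) enclosing a small off-center nodule. Ground truth marks lesion
pixels only; the hollow's interior is background class. Gaussian noise
(σ as a fraction of the [0, 1] range) and a smooth sinusoidal bias field
are added after rasterization. Placement samples nodule centers uniformly
from the exactly-feasible pixel set (inside a lung with margin, clear of
existing lesions), so generation is deterministic per seed and fails only
when no feasible position exists.

The packaged seed map places one foreground seed at each lesion's
representative point, background seeds on a sparse grid away from lesions,
and one background seed inside the hollow interior. The interior seed
matters: the interior is enclosed by the high-contrast wall, so without a
seed there the harmonic solve would assign it the wall's label — exactly
what an interactive user would correct with one extra click. Intensity
levels were chosen so that both the walker and the hybrid mode recover the
noise-free truth exactly (the test suite requires Dice ≥ 0.95).

The IHC phantom scatters non-overlapping round cells (radius 3–5 px,
default 400 cells on 320×320 px) and flags each positive independently with
probability p (default 0.19, matching the low end of reported
positive-cell proportions for combination-treated tissue). Positive cells
get a staining-intensity category 1–3 and render darker in the stain
channel; a counterstain channel shows all cells. The per-cell table is the
ground truth; over many seeds the realized positive fraction is binomially
consistent with p (tested over 200 phantoms).

What the phantoms do *not* emulate: realistic CT texture and artifacts,
partial-volume effects, anatomic variability, stain deconvolution, touching
or overlapping cells. Passing tests therefore demonstrate algorithmic
correctness on controlled geometry, not clinical performance on real
scans or slides.

## IHC statistics (`rwct.ihc_stats`, `rwct.tables`)

The immunohistochemical score (IHS) combines a staining-intensity category
(0–3) with a positive-cell proportion category (0–4: <5%, 5–25%, 25–50%,
50–75%, >75%). The default convention is the product (range 0–12), which is
consistent with the score values {1, 2, 4, 6} observed in the packaged
tables; an additive convention (0–7) is selectable.

Published group summaries (mean ± sample SD, n = 5 per group) are bridged
to raw scores by exhaustive enumeration of all integer 5-multisets over
0–12 whose mean (2 dp) and sample SD (printed precision) round to the
printed values. Ambiguity across groups is resolved jointly: over the
Cartesian product of candidates, only assignments reproducing the table's
published tie-corrected H and every published pairwise mean-rank
difference at 3 dp survive, and the survivors must be unique up to
rank-equivalence (identical pooled rank structure). For all three packaged
markers this selects exactly one assignment.

Kruskal–Wallis uses pooled average ranks with the tie correction
C = 1 − Σ(t³−t)/(N³−N); an all-tied sample returns H = 0 by convention.
Dunn's post-hoc test uses pooled mean ranks (no pairwise re-ranking), the
tie-adjusted SE = sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)),
two-sided normal p-values and Bonferroni correction with m = k(k−1)/2 = 6
for four groups. Published tables in this area sometimes print the pairwise
mean-rank difference under the symbol "H"; it is not a two-group
Kruskal–Wallis statistic (which cannot exceed ~6.8 for two groups of five)
and is labelled D here.

## Problem sizes and runtime choices

Phantom segmentation runs at 80×80 px (6 400-pixel graphs, ~12 700
lattice edges), where the direct sparse solve and the exact max-flow each
finish in well under a second. Oracle-equivalence checks run on all lattice
shapes up to 10×10 against dense solves, cut optimality on random instances
up to 12 pixels against 2^n enumeration, and Hausdorff on masks up to 12×12
against all-pairs enumeration. Statistical reconstruction enumerates
C(18, 5) = 8 568 multisets per group and at most 16 joint combinations per
table, all in milliseconds.

## Known limitations

- 2D single-slice only; DICOM series and 3D volumes are out of scope.
- Seed placement is manual (or packaged for phantoms); no automatic seeding.
- The pure-cut mode's histogram prior is intensity-only and weak by design.
- The score reconstruction assumes integer scores on 0–12 and sample SD
  with divisor n−1; both assumptions are validated by the packaged tables
  but would need revisiting for other scoring schemes.
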