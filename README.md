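# rwct

Seeded segmentation of 2D grayscale (CT-like) images by the random-walker
method, optionally sharpened by an s-t minimum-cut stage, together with the
standard evaluation metrics (Dice, Hausdorff) and the rank-based statistics
used to compare immunohistochemical scores between treatment groups.

## Who this is for

Researchers who need (a) an interactive, seed-driven segmenter for single
CT slices or other grayscale rasters, (b) reproducible Dice/Hausdorff
scoring of segmentations against a gold standard, and (c) a transparent
reimplementation of the tie-corrected Kruskal–Wallis test with Dunn
post-hoc comparisons as applied to small-n ordinal immunohistochemistry
(IHC) score tables — including the ability to recover raw integer score
vectors from published mean ± SD summaries.

## The methods

**Random walker.** An image is mapped to a weighted graph *T = (W, F)* with
one node per pixel and Gaussian edge weights
*v<sub>ij</sub>* = exp(−β (t<sub>i</sub> − t<sub>j</sub>)²)
on lattice-adjacent pixels (intensities rescaled to [0, 1] by default, so β
is image-scale-free). The probability that a walker from pixel *i* first
reaches the seeds of label *L* is a combinatorial harmonic function: it
solves the discrete Laplace equation ∇²o = 0 at unseeded nodes with seeds
as Dirichlet boundary values, i.e. one sparse SPD linear system
*L<sub>uu</sub> x = −L<sub>us</sub> b* per label, where *L* is the graph
Laplacian (also exposed via its incidence-matrix factorization
*B*ᵀdiag(*v*)*B*). Each pixel takes the label with the largest probability.

**Hybrid cut stage.** The pixel graph is augmented with terminals *Q*
(source/foreground) and *I* (sink/background): n-links carry capacity
λ<sub>n</sub>·*v<sub>ij</sub>*, and each pixel's t-links carry the negative
log of the opposite class's posterior probability (from the walker), with
seeds hard-linked. The exact minimum-weight cut (= maximum flow) gives a
spatially regularized segmentation; as λ<sub>n</sub> → 0 it reduces to the
walker's argmax.

**Metrics.** Dice = 2|R₁∩R₂|/(|R₁|+|R₂|); Hausdorff distance =
max of the two directed max-of-min Euclidean distances between foreground
pixel centers (spacing-aware, with a percentile variant, e.g. HD95).

**IHC statistics.** Group score vectors are compared with the
tie-corrected Kruskal–Wallis statistic
*H* = [12/(N(N+1)) Σ R<sub>g</sub>²/n<sub>g</sub> − 3(N+1)] / *C*,
*C* = 1 − Σ(t³−t)/(N³−N), followed by Dunn's pairwise comparisons on pooled
mean ranks, *z* = |R̄<sub>i</sub> − R̄<sub>j</sub>| / SE with the
tie-adjusted SE, Bonferroni-corrected over m = k(k−1)/2 pairs. When only
mean ± SD summaries are published, the raw integer multisets are recovered
by exhaustive enumeration and disambiguated against the published
statistics.

No external data are needed: a phantom module generates CT-like slices
(lung fields, nodules, an eccentric hollow cavity) and IHC-like stained-cell
fields with ground truth, deterministically per seed.

## Worked example

```bash
rwct phantom ct --seed 7 --out ph/            # synthetic slice + truth + seeds
rwct segment --image ph/image.png --seeds ph/seeds.csv --mode hybrid --out seg/
rwct eval --pred seg/mask_label2.png --truth ph/truth.png --metrics dice,hd,hd95
```

prints

```
{"dice": 1.0, "hd": 0.0, "hd95": 0.0}
```

— on the noise-free phantom the hybrid segmentation recovers the lesion
mask exactly (Dice 1 means perfect overlap; Hausdorff 0 means the boundaries
coincide).

```python
>>> from rwct import tables, kruskal_wallis, dunn_pairwise
>>> scores = tables.packaged_group_scores("hif1a")   # reconstructed from mean±SD
>>> scores
{'M': (6, 6, 6, 6, 6), 'W': (4, 4, 4, 4, 4), 'C': (4, 6, 6, 6, 6), 'C+W': (2, 2, 4, 4, 4)}
>>> kw = kruskal_wallis(scores)
>>> round(kw.h, 3), round(kw.p_value, 3)
(15.472, 0.001)
>>> res = dunn_pairwise(scores, ("C+W", "M"))
>>> round(res.d, 3), round(res.p_adjusted, 3)
(11.2, 0.006)
```

Here H = 15.472 (p = 0.001) says the four treatment groups differ in their
HIF-1α immunohistochemical scores, and the combination-therapy group (C+W)
differs from the untreated model group (M) with a pooled mean-rank
difference of 11.2 (Bonferroni-adjusted p = 0.006).

The same analysis is available from the shell:

```bash
rwct ihc-stats --table table1.csv --marker hif1a --pairwise --out report.json
```

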