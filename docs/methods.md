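# Methods

## Pipeline model and assumptions

`angiograph` treats a tube-formation image as a planar spatial network: the
binary tubule mask is assumed to be a faithful footprint of the vessel-like
structures, its 1-px skeleton a faithful centerline, and the 8-adjacency
pixel graph (edges weighted by Euclidean inter-pixel distance, 1 or √2) a
faithful discretization of network geometry. The framework is strictly 2-D
and binary: lumen diameter, intensity, and out-of-plane structure carry no
weight. Metrics are therefore topology/geometry summaries of the centerline
network, not of vessel caliber.

## Segmentation

* **Grayscale**: BT.709 luminance weights (0.2125, 0.7154, 0.0721), the
  scikit-image convention; the weights sum to 1, so intensity scale is
  preserved and equal-channel images are unchanged.
* **Smoothing**: Gaussian, σ = 1 px by default, reflect padding (keeps
  constant images exactly constant at borders). σ = 0 is a strict identity.
* **Binarization**: Otsu's threshold on the smoothed histogram. Otsu fixes a
  cut, not a polarity; tubules occupy a minority of the field in these
  assays, so the minority-fraction side is foreground by default
  (`invert_foreground` flips it). A constant image has no threshold: the
  pipeline returns an all-background mask with a warning rather than
  aborting a batch.
* **Cleanup**: 8-connected components with *fewer* than 64 px are removed
  (strict: exactly-64-px components survive). 8-connectivity matches the
  graph construction's neighborhood. Cleanup is idempotent.

Images are processed at native resolution; no resizing.

## Graph construction

One node per skeleton pixel, coordinates kept as node attributes
((row, col), 0-based; x = col, y = row is the single plotting conversion).
Adjacency is decided on integer Chebyshev distance 1 by scanning the fixed
half-neighborhood E, SE, S, SW per pixel — O(n) and duplicate-free — which
is provably edge-set-identical to thresholding the full pairwise Euclidean
distance matrix at √2 (the definitional form); the test suite checks this
equivalence against a brute-force O(n²) oracle. The scan form is used for
memory safety on ~10⁵-pixel skeletons.

## Metrics: numerical choices

* **Clustering** uses the standard Watts–Strogatz per-node form
  C_v = 2T_v / (k_v(k_v−1)) with C_v = 0 for degree < 2, averaged over all
  nodes; triangles are counted unweighted.
* **Shortest paths** are weighted by the Euclidean edge weights for
  efficiency, betweenness and tortuosity — tortuosity requires geometric
  path length, and the same convention is applied to the other two for
  internal consistency. `MetricConfig(weighted_paths=False)` switches all
  three to hop counts.
* **Efficiency** counts disconnected ordered pairs as 0 (1/∞), so fragmented
  early networks are handled without special-casing.
* **Betweenness** is normalized by (|V|−1)(|V|−2)/2 (undirected convention),
  making values comparable across images of different size; graphs with
  < 3 nodes have no interior vertices and score 0.
* **Tortuosity** is the mean of L_ij / D_ij over up to 100 (default)
  distinct unordered node pairs drawn uniformly, seeded, from
  *same-component* pairs only (cross-component tortuosity is undefined).
  When fewer valid pairs exist than requested, all pairs are used, making
  the estimate exact. Sampling is component-weighted rejection sampling,
  deterministic given `rng_seed`.
* **Degenerate graphs**: efficiency/density on a singleton and tortuosity on
  an edgeless graph are NaN sentinels (logged), never fabricated zeros; an
  empty graph raises.

## Radial zone analysis

Center = ((width−1)/2, (height−1)/2) — symmetric for odd and even
dimensions. Zone index k = ⌊d/Δr⌋ + 1 with Δr = 50 px and 6 zones by
default; a distance exactly on a boundary belongs to the outer zone (floor
semantics). Nodes beyond the outermost zone are excluded from the profile
but counted (`n_excluded`), so nothing is silently dropped. Densities are
counts over annular areas π Δr² (2k−1).

Heterogeneity statistics are computed on the area-normalized densities:
population SD (sample SD switchable), Shannon entropy in nats of the
density-mass distribution p_k = density_k / Σ density (zero zones contribute
zero; the maximum ln 6 ≈ 1.792 is attained exactly at uniformity), CV =
SD/mean, gradient = density₁ − density₆, and the OLS slope of density
against zone index. Entropy and CV are scale-free; SD, gradient and slope
scale linearly with density.

## Statistics

Mann–Whitney U: exact enumeration when min(n, m) ≤ 8 and the pooled sample
is tie-free (matching the small-replicate designs these assays use,
n = 6–9), otherwise the tie-corrected normal approximation with continuity
correction. Cliff's delta magnitude classes use |δ| with cut-points
0.147 / 0.33 / 0.474; boundary values fall in the lower class. ROC-AUC uses
raw metric values as scores with group B (e.g. "dense") as the positive
class; since AUC = U/(nm), δ = 2·AUC − 1, identities the tests verify on
random draws. The flipped AUC max(AUC, 1−AUC) is reported because
discriminability is direction-free: a metric that is systematically *higher*
in the reference group separates groups just as well. Raw p-values are
reported by default (per-metric tests); Benjamini–Hochberg adjustment is
opt-in. Which metrics to normalize per node is a caller-supplied list
(default: none — the `avg_*` metrics are already per-node averages).

## Synthetic generator

The generator emulates the polygonal capillary-like meshes of
tube-formation assays: `n_seeds` integer-coordinate points (minimum
separation 3× tube width) scattered over the canvas, joined by their
Delaunay-triangulation edges, drawn as dark (grey 40) tubes of width 5 px
on a bright (grey 220) background — brightfield polarity, which exercises
the foreground-polarity logic. `fragmentation` deletes that fraction of
mesh edges, emulating early-timepoint fragmented networks;
`noise_level` sprinkles specks of ≤ ~38 px (always below the 64-px cleanup
threshold, and never part of the ground truth). The minimum seed separation
guarantees every true network fragment exceeds the cleanup threshold, so
ground truth survives preprocessing. All geometry is integer and driven by
one seed: identical configs give bit-identical images.

Presets encode the two seeding-density morphologies: `sparse` (8 seeds,
fragmentation 0.25) and `dense` (40 seeds, fragmentation 0). On a 512×512
canvas these produce a few hundred vs. several thousand skeleton nodes.
Tests and the acceptance script run the generator on scaled-down canvases
(128–256 px) so that the all-pairs path metrics stay cheap; the contrasts
they verify are scale-free directions (more nodes, more components, lower
connectivity index), not absolute values.

What the generator does **not** emulate: intensity gradients and uneven
illumination, out-of-focus blur, cell bodies and debris larger than the
cleanup threshold, curved tubes (mesh edges are straight, so absolute
tortuosity values are lower than in real assays), or anisotropic growth.
Passing tests therefore demonstrate correctness of the measurement chain
on networks with known topology — not segmentation robustness on difficult
real images, which remains limited by Otsu thresholding on low-contrast
data.

## Known limitations

* Otsu segmentation can fail on low-contrast or unevenly lit images;
  errors propagate to the skeleton and graph.
* Pixel-level nodes make |V|, |E| resolution-dependent; compare absolute
  counts only across images of equal scale, or normalize per node.
* All-pairs path metrics (efficiency, betweenness) cost O(|V|·|E|) and
  dominate runtime beyond ~5·10³ nodes.
* The radial analysis assumes the biologically meaningful origin is the
  image center; off-center fields need cropping or a custom center.
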