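# Methods

## Problem and model

A stained bone-marrow field contains four kinds of pixels: plasma-cell
nuclei, plasma-cell cytoplasm, background, and unstained cells. The package
segments plasma cells (nucleus ∪ cytoplasm) instance-by-instance, in four
stages.

**Region color model.** Every image is expanded into nine channels
(R, G, B, H, S, V, L, a, b), all rescaled to [0, 255] (hue maps the full
circle; L maps [0, 100]; a, b map [−128, 127]). Each (region, channel) pair
is modeled as a univariate Gaussian fitted by sample moments from labeled
pixels — moments are the maximum-likelihood fit and need no histogram
binning. Separability of two regions in a channel is the closed-form
Gaussian Bhattacharyya distance; the package also cross-checks this closed
form against numerical quadrature of −ln∫√(pq) in the test suite.

**Channel weighting.** A channel represents a region only if it separates
that region from *both* of its competitors (nucleus ↔ {cytoplasm,
background}; cytoplasm ↔ {nucleus, background}; background and unstained ↔
{nucleus, cytoplasm}). Thresholds: 1 for the two plasma-cell regions, 3 for
background and unstained cells, compared non-strictly (≥); the assigned
weight is the larger of the two distances. The non-strict comparison is
deliberate: the reference distance table contains a pair distance of
exactly 1.00 whose channel does carry a weight in the reference weight
table, so a strict rule would not reproduce it.

**Level set.** Four phases are the sign patterns of two fields φ₁, φ₂.
The energy combines the negative log of per-region probability maps
(weighted mixtures of channel Gaussians, floored at 1e−12 so logs stay
finite) and per-region distance images (weighted squared deviation from
region channel means), plus optional area terms and contour-length
regularizers. Minimization is explicit Euler–Lagrange descent with the
arctan-smoothed Heaviside (ε = 1.5 px), curvature by central differences
with |∇φ| floored at 1e−8, and re-initialization of both fields to the
exact Euclidean signed distance of their zero sets every 20 iterations
(computed from distance transforms with a half-pixel offset; deterministic,
unlike PDE re-initialization).

One numerical choice matters: the distance images are in squared 8-bit
intensity units, so the raw descent force reaches ~10⁴–10⁵ and a fixed time
step would explode. The combined force (data + area + curvature) is
therefore rescaled once per run by the 99th percentile of its initial
magnitude. Because the *whole* force is scaled by one constant, this is a
pure reparametrization of descent time: stationary points, the energy
landscape, and the descent property are unchanged; only the meaning of one
"iteration" is normalized across images. With dt = 0.5 the maximal
per-iteration displacement is then ≈ dt/(πε) ≈ 0.1 px at the interface,
and 500 iterations suffice for the front to travel from the seed circles to
the cell boundaries on the scene sizes used here.

Initialization is a lattice of small circles covering the image (signed
distance to the union), the φ₂ lattice offset by half a spacing so the two
fields break symmetry. At full smear resolution (min dimension 1920) the
defaults are radius 8 / spacing 24; smaller images scale proportionally
with a floor of radius 5, spacing 3·radius.

**Post-processing.** Components of the stained mask below 200 px are
discarded (staining debris), as are components whose cytoplasm area
(component minus nuclei) is below 10% of the median component area
(lymphocyte-like). Clusters are split in two watershed passes. The nuclei
mask comes either from 2-cluster k-means on the (B, H, V) features of
stained pixels — the channels where nucleus and cytoplasm separate — taking
the darker-in-V cluster, or directly from the nucleus phase; a light
cleanup (disk-2 opening, 30 px speckle floor) precedes marker extraction,
because ragged mask boundaries otherwise over-seed the watershed. Nuclei
markers are h-maxima of the distance transform (saddle depth ≥ 2 px), and
watershed regions whose centroids lie closer than 1.4× the typical nucleus
radius are merged back: two real nuclei in a cluster are at least
(2 − 2·overlap)·r_cell ≈ 1.4 r_cell apart, while an irregular single
nucleus fragments into lobes only a few pixels apart. Cells are then split
by watershed on the stained-mask distance transform with minima imposed at
nucleus centroids (3 px disks). After each watershed, only regions
containing a circular-Hough center are retained. The CHT runs on the mask
boundary with radii 0.25–1.5× the typical (area-weighted median) component
radius and sensitivity 0.3 on the circumference-normalized accumulator: a
cell inside a 2-cell cluster exposes only ~70–75% of its circle and its
boundary is irregular, which puts genuine cells at scores ≈ 0.35–0.6.
Finally, instances with nucleus/cell area ratio > 0.85 are rejected as
lymphocyte-like.

## Synthetic scenes

The generator emulates a Jenner-Giemsa-stained field: mildly perturbed
circular cells (radial perturbation ≤ 10%, radius 11–14 px on a 256² canvas)
with eccentric inner nuclei (55–75% of the cell radius), clusters whose cell
centers sit (2 − 2·overlap)·r apart (overlap 0.3), pale background, and
unstained cells. Colors are sampled per pixel from per-region RGB Gaussians
plus sensor noise; the derived channels emerge through the forward
conversions so all nine stay mutually consistent. The default palette —
nucleus (105, 78, 140) σ6, cytoplasm (92, 92, 168) σ7, background
(225, 200, 235) σ8, unstained (230, 215, 100) σ8 — is tuned to reproduce
the separability pattern of real smears: nucleus vs cytoplasm D_B ≥ 1 only
in B, H, V; unstained cells far from stained regions in hue (8-bit hue
< 120, background ≥ 120). The unstained palette is deliberately *saturated*
tan (dark in B): real fields contain dark content in every channel, and
without it the per-channel 1% contrast stretch would crush the blue
histogram and rotate stained-pixel hue below the unstained-removal cut.

What the scenes do not emulate: staining texture inside nuclei and
cytoplasm (real chromatin is heterogeneous), out-of-focus blur,
illumination gradients, stain batch variation, and non-circular or
deformed cells. Passing the synthetic-recovery tests therefore shows the
pipeline's logic is correct under its own modeling assumptions, not that
clinical performance is reproduced; the clinical benchmark figures quoted
in `plasmaseg.reference` come from the original 85-image evaluation and
are used only for arithmetic checks.

## Default study conditions

The default scene is 256×256 px with 20 plasma cells (14 singles, three
2-cell clusters) and 3 unstained cells, ~20% cell cover — a dense but
feasible field at the package's working scale. The synthetic-recovery
check runs the k-means variant over ten such scenes (seeds 1–10, model
fitted on an independent seed-1000 scene) and pools counts before computing
metrics, the same micro-averaging used for the benchmark tables. Problem
sizes throughout the tests (128²–256² images, 200–500 level-set
iterations) were chosen as the smallest at which every stage behaves as at
full scale.

## Evaluation

Predictions match ground-truth cells by greedy descending-IoU one-to-one
matching; a truth cell is recovered only at IoU ≥ 0.7 ("completely
segmented" — partial or over-segmented cells count as misses). TPR, PPV,
F1 and FDR are reported as percentages rounded to two decimals; FDR is the
exact complement of PPV before rounding. Greedy matching rather than
optimal assignment: at these cell densities ties across candidates are
rare, and greedy matching is simpler to audit.

## Known limitations

* The pipeline assumes stain-normalized input; no illumination or stain
  correction is performed.
* Hue circularity is ignored at the unstained-removal threshold (plain `<`
  on the rescaled plane); stains whose hue straddles 0° would need a
  circular rule.
* The color model is unimodal per channel; heavily textured nuclei violate
  it and would need mixture or kernel densities.
* The CHT circularity gate rejects strongly elongated or ruptured cells by
  design; recall on such cells is zero.
* Two-function encoding caps the number of phases at four.
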