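# Methods

This note documents the models and numerical choices behind `lungfield`, in
the order the pipeline runs them, together with what the synthetic phantom
does and does not establish about behaviour on clinical CT.

## Structure-tensor edge indicator

For a slice `I`, gradients are central differences with replicate
(edge-clamp) boundaries.  The structure tensor
`J_σ = K_σ * [[Ix², IxIy], [IxIy, Iy²]]` is smoothed with a truncated,
unit-sum Gaussian whose support is fixed at 3×3 (σ = 3 by default even though
that σ would normally imply a wider support; both are configurable via
`EdgeParams`).  The eigenvalue gap has the closed form
`T = √((Jxx−Jyy)² + 4Jxy²)`; it is ≈ 0 in flat regions and large on edges and
corners.  The binary map is `g* = 1` where `T > T_c` with
`T_c = mean(T) + κ·std(T)` (population std, statistics over **all** pixels,
ties map to non-edge).  Defaults: σ = 3, κ = −0.05, kernel 3×3.

**Convention.**  `g*` marks edges with 1 — the *opposite* of the classical
edge-stopping function `g = 1/(1+|∇(G_σ*I)|²)`, which is ≈ 0 on edges.  The
segmentation therefore uses `w = 1 − g*` wherever a classical `g` would
appear (`invert_edge_map=True`, the default): the TV length term is penalised
*away* from detected edges, bulk pixels are driven by the global intensity
term, and edge-band pixels by the local term, which is what lets the local
fit refine the boundary without costing the model its global-minimum
property.  The literal convention (`invert_edge_map=False`: global term on
edge pixels only) is kept selectable; under it the local term — which carries
no information far from the current contour — governs the bulk, and the
result becomes initialisation-dependent.

## Convex global+local segmentation by split Bregman

Energy over the relaxed indicator `φ ∈ [0,1]`:

    E(φ) = ∫ w |∇φ| dx + μ ∫ φ s dx,          s = −(F₁ + F₂)
    F₁ = α′ w (−(I−c₁)² + (I−c₂)²)             (global / CV term)
    F₂ = β′ (1−w) (−e₁ + e₂)                   (local / LBF term)

with region means `c_i` weighted by `M₁ = φ`, `M₂ = 1−φ` (the regularised
Heaviside `H_ε` and Dirac `δ_ε`, ε = 1, are implemented for the non-convex
formulation but are not used in the convex solver: with ε = 1 they would
compress `[0,1]` into a narrow band), local fitted intensities
`f_i = K_ω*(M_i I) / K_ω*(M_i)` with a unit-sum Gaussian window of support
`(4ω+1)²` (ω = 1), and local fit energies
`e_i = I²(K*1) − 2I(K*f_i) + K*(f_i²)`.  Where `K_ω*(M_i)` vanishes, `f_i`
falls back to `c_i` — this matters: deep inside a phase the *other* phase's
local fit is undefined, and the fallback is what gives far-from-contour
pixels a sensible comparison value.

Split Bregman introduces the auxiliary field `d ≈ ∇φ` and Bregman variable
`b`.  Each outer iteration: refresh `c_i, f_i, e_i, s`; one Gauss–Seidel
sweep (configurable `n_inner`) of

    φ_ij = clamp( (Σ_nbr φ + α_ij − (μ/λ) s_ij) / n_ij , 0, 1 )

where `α` is the negative backward divergence of `d − b` over existing grid
edges and `n_ij` is the number of incident grid edges (4 in the interior —
the printed quarter-stencil — 3 or 2 on the frame border); then
`d ← shrink(b + ∇φ, w/λ)` on the per-pixel 2-vector magnitude and
`b ← b + ∇φ − d`.  The gradient uses forward differences with replicate
boundary.  The sweep is exact projected coordinate descent of the augmented
quadratic, so with fixed coefficients the objective is monotonically
non-increasing, any constant `φ` is a fixed point of the homogeneous problem,
and pixels pinned at 0/1 by the clamp act as Dirichlet anchors that make the
`d = b = 0` subproblem a well-posed anchored Poisson solve.  The sweep is the
one sequential hot spot and is compiled with numba (the pure-Python sweep is
retained and tested for exact agreement).

Defaults follow the reference setting: α′ = 0.9, β′ = 0.1, λ = 10³, μ = 3λ,
ω = 1, ε = 1.  Convergence: mean |Δφ| < 10⁻⁴ or 200 outer iterations.
Initialisation thresholds the image at −500 HU (lung is radiolucent);
because the energy is convex the initialisation affects only run time, which
the invariance tests confirm.  Since HU magnitudes make `μ·s/λ` dominate the
stencil, the iteration behaves like an adaptively re-fitted thresholding and
typically converges in a handful of outer iterations.

**Orientation.**  The two-phase energy is exactly symmetric under
`(φ, c₁) ↔ (1−φ, c₂)`.  The returned foreground is always the lower-mean
(radiolucent) phase (`orient_mask=True`), so differently initialised runs
are comparable; the −500 HU initialisation implies the same orientation.

The mask is `φ > 0.5`.  Post-processing: foreground components touching the
frame border are removed (the air outside the body is also below −500 HU),
then interior holes (vessels, the hole a high-density nodule punches) are
filled morphologically.

## Airway exclusion

Two rules, both over 8-connected components:

* **Osseous neighbourhood** — dilate the component by a disk
  (radius 8 px), and count pixels above 200 HU in the dilation ring;
  fewer than 20 ⇒ the component is not near ribs ⇒ removed.  The three
  thresholds are not prescribed by the underlying model; they are chosen so
  that rib density (≳ +300 HU) is decisive while partial-volume blur is
  tolerated, and all are configurable.
* **Previous-slice propagation** — forward pass from slice 2: a component is
  removed when more than `overlap_fraction` (default 0.5) of its footprint
  was excluded on the previous processed slice (present in the pre-exclusion
  mask, absent after).  This catches slices where a tracheal cartilage ring
  passes the osseous test; stacks are assumed rigidly aligned (no
  registration), and propagation is forward-only — the backward direction
  would require a second pass and is not implemented.

Exclusion only ever removes pixels and is idempotent slice-wise.

## Fractal defect detection

The minimum enclosing rectangle of the mask is tiled into 10×10 blocks when
at least two lung subregions remain, 2×2 otherwise (one lung means blocks
would halve in width and become too small to carry the box-counting ladder);
remainder pixels go to the last block row/column, so the blocks tile the
rectangle exactly and every boundary pixel belongs to exactly one block.
The boundary is the set of foreground pixels with a background 4-neighbour.
For each boundary-containing block, `N(s)` counts boxes of side
`s = 2^k, …, 2` (largest power of two ≤ the block's shorter side, anchored at
the block's top-left corner; at least three scales are required, so blocks
must be ≥ 8 px on the short side) that intersect the boundary, and `D` is the
least-squares slope of `log N(s)` against `log(1/s)`.  A straight segment
gives `D ≈ 1`, a filled block `D ≈ 2`, a single pixel `D ≈ 0`.  Blocks with
`D > T_f = mean(D) + m·std(D)` (sample std over boundary blocks; multiplier
`m = 1` by default, exposed because the threshold is ultimately an empirical
choice) are flagged defective.  A juxtapleural indentation roughly triples
the boundary content of its blocks at fine scales, which reliably puts them
in the flagged tail; a statistical threshold necessarily also flags a small
upper tail of smooth blocks (harmless: the correction holds anchored
boundaries still).

## Boundary correction

The image is partitioned into Ω₁ (outside the lung, outside defective
blocks; speed code k = +1), Ω₂ (lung interior; k = −1), Ω₃ (boundary pixels
in non-defective boundary blocks; k = 0), Ω₄ (the full footprint of every
defective block; k = −1).  The contour is the zero set of a signed field φ
(+c inside, −c outside, c = 2, smoothed once); with this inside-positive
convention the evolution uses outward normal speed `−k`, so k = −1 expands
and k = +1 shrinks.  One iteration:

    φ ← φ + Δt [ (−k)|∇φ|  +  κ₁(n) δ_ε₁(φ) div(∇φ/|∇φ|)  +  κ₂ δ_ε₁(φ) ]

with Godunov upwinding for the balloon term (growth takes the ∇⁻ switch so
maxima stay stationary), central differences for curvature (|∇φ| floored at
10⁻⁸), `κ₁(n) = 5n` capped, κ₂ = 0.1 expanding outward (the area term's sign
is convention-dependent and exposed as `area_term_sign`), ε₁ = 0.5 — then the
regularisation that replaces signed-distance reinitialisation: φ is reset to
±c by its sign and convolved with a unit-sum Gaussian (σ₁).  The binary reset
is essential: plain repeated convolution flattens φ, widens the effective
Dirac band and inflates the curvature speed (which divides by |∇φ|) until the
length force tears the contour off its k = 0 anchors.

Numerical parameters and why:

* `Δt = 0.3` — below the unit-balloon CFL limit, but large enough that one
  binary-reset cycle can flip a contour-adjacent pixel (with Δt = 0.1 the
  update never crosses zero before the reset discards it and the balloon
  stalls inside the indentation).
* `κ₁ cap = 30` — `κ₁ = 5n` grows without bound as printed; the cap keeps the
  length force `κ₁ δ(0) κ_curv` below the unit balloon force at lung-boundary
  curvature radii ≳ 20 px, so smoothing never overpowers the anchors, while
  in the indentation (concave, radius ≈ 8 px) curvature still actively helps
  the fill.
* `σ₁ = 0.75` — sub-pixel smoothing keeps the rounding of anchored corners
  within ~2 px.
* Stopping — the contour is stationary when the fraction of sign-changing
  pixels stays below 10⁻⁴ for five consecutive iterations, **or** when the
  sign pattern exactly repeats the one from two iterations earlier for five
  consecutive iterations: where opposing balloon codes sandwich the 1-px
  anchor line the discrete contour settles into an exact period-2 flicker,
  which is a stationary contour, not a failure to converge.  Hitting
  `max_iters` (300) returns the last state with a warning flag.

The corrected mask is `φ > 0` (ties outside).  Within a defective block the
balloon also pushes slightly beyond the original boundary; the equilibrium
bulge height is ≈ w²/(8R) ≈ 2 px for block width w ≈ 17 px and the
curvature-balance radius R ≈ κ₁ δ(0) ≈ 19 px, which is why corrected masks
agree with the nodule-inclusive truth to Dice ≈ 0.99 rather than exactly.

## Phantom

The generator draws, at configurable HU plateaus (−1000 outside air, −800
lung, +40 soft tissue, +400 bone, 10 HU seeded Gaussian noise), a body
ellipse, two lung ellipses, rib blobs offset 6 px from the lung margin (three
per lung), an air-filled trachea disk away from any bone, an optional
cartilage ring around the trachea on chosen slices (default: the middle slice
of a 3-slice stack), and juxtapleural nodules as soft-tissue disks centred on
the lung boundary, which carve half-disk indentations out of the
segmentation-truth mask.  Geometry is deterministic; only the noise is
seeded, per (seed, slice).

What it establishes: correctness of every pipeline rule on inputs where the
ground truth is exact — HU separability, rib adjacency, cartilage-only
slices, indentation shape and area.  What it does not: clinical CT has
partial-volume blur, vessels and bronchi inside the lung, breathing and
cardiac motion, scanner noise texture, and anatomical variation, none of
which the phantom models — passing tests demonstrate the algorithms, not
clinical-grade accuracy.

## Problem sizes

Tests and the acceptance script run on 256×256 3-slice phantom stacks,
128×128 two-phase images, 64×64 edge/inhomogeneity fixtures, and 8×8 solver
oracles; the full suite completes in seconds on one CPU.  All sizes are
package choices and scale up transparently (the solver is linear per sweep in
pixel count).

## Known limitations

* Slice-wise 2D only; no 3D level set, no 3D surface reconstruction.
* Airway exclusion removes already-segmented components; it does not trace
  the bronchial tree.
* Defect detection requires at least two boundary blocks and blocks ≥ 8 px
  on the short side; a single-lung field falls back to a coarse 2×2 grid.
* The fractal threshold `T_f` flags the statistical upper tail even on
  perfectly smooth boundaries (by construction); downstream anchoring makes
  such false positives nearly free, but they are reported.
* No re-detection loop after correction: a defect the detector misses stays
  uncorrected.
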