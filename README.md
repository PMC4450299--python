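# lungfield

Lung-field extraction from thoracic CT slices, with automatic re-inclusion of
juxtapleural nodules.

Intensity-based lung segmentation on CT works because lung parenchyma
(≈ −800 HU) is far more radiolucent than the chest wall (≈ +40 HU).  It fails
in two systematic ways: the central airway is air-filled and gets kept with
the lungs, and juxtapleural nodules — nodules attached to the pleura, with
soft-tissue density — get carved *out* of the lung field, which is
unacceptable for nodule CAD since precisely these nodules have a high
malignancy rate.  `lungfield` implements a complete pipeline addressing both:

1. **Edge detection** — a binary indicator `g*` from the structure tensor
   `J_σ = K_σ * (∇I ∇Iᵀ)`: the eigenvalue gap `T = ρ₁ − ρ₂` is thresholded at
   `T_c = mean(T) + κ·std(T)`, giving edges that are robust to noise where the
   classical `g = 1/(1 + |∇(G_σ*I)|²)` is not.
2. **Segmentation** — a globally convex two-phase model combining the
   piecewise-constant (Chan–Vese) energy, the local binary fitting (LBF)
   energy through a Gaussian window `K_ω`, and an edge-weighted total
   variation length term, minimised by split Bregman iteration with the
   relaxed indicator `φ` clamped to `[0, 1]`:

       min_{φ∈[0,1]}  |∇φ|_g + μ ⟨φ, s⟩,     s = −(F₁ + F₂),
       F₁ = α′ w (−(I−c₁)² + (I−c₂)²),   F₂ = β′ (1−w) (−e₁ + e₂),

   where `c_i` are the global region means, `e_i` the local fit energies, and
   `w` the edge-derived weight.  The convex energy has a global minimiser, so
   the result does not depend on the initial contour; the mask is the 0.5
   superlevel set of `φ`.
3. **Airway exclusion** — components whose dilated neighbourhood contains no
   osseous-density pixels (the lungs are hugged by ribs; the trachea is not)
   are removed, and a forward pass over the slice stack removes components
   whose footprint was excluded on the previous slice (catching slices where
   a tracheal cartilage ring mimics bone).
4. **Defect detection** — the lung bounding box is tiled into 10×10 blocks
   (2×2 for a single lung region); each boundary-containing block gets the
   box-counting fractal dimension `D` of its boundary (slope of `log N(s)`
   vs `log 1/s`); blocks with `D > T_f = mean(D) + std(D)` are defective —
   a juxtapleural indentation makes the boundary locally convoluted.
5. **Boundary correction** — a region-coded geometric active contour:
   speed code `k` is 0 on correct boundary pixels (anchors), −1 inside the
   lung and throughout defective blocks (balloon expansion fills the
   indentation), +1 outside (shrink back), plus a curve-length and an area
   force, regularised each iteration by a binary reset and Gaussian
   convolution.  The indentation is refilled while the rest of the boundary
   stays put.

A synthetic CT phantom (body, lungs, ribs, trachea with optional cartilage
ring, juxtapleural nodule indentations, seeded noise) with ground-truth masks
makes the whole pipeline testable offline; DICOM series, NIfTI volumes and
PNG/TIFF-with-rescale inputs are supported for real data.

## Worked example

```python
from lungfield import LungFieldModel, PhantomSpec
from lungfield.model import dice_coefficient

model = LungFieldModel.from_phantom(PhantomSpec(seed=7))
res = model.fit()
print(res.summary())

truth = model.ground_truth[0]
notch = truth.lung_with_nodules & ~truth.lung_without_nodules
corrected = res.masks_corrected[0]
print("corrected-vs-truth Dice =",
      round(dice_coefficient(corrected, truth.lung_with_nodules), 4))
print("nodule indentation refilled =",
      round((corrected & notch).sum() / notch.sum(), 3))
```

prints

```
Lung-field extraction results
====================================================================================
slice segit conv        c1        c2 regions defects corrit cconv area_pre area_post
------------------------------------------------------------------------------------
    0     1    T    -927.2      48.6       2       4     27     T    16601     16575
    1     1    T    -927.2      52.6       2       4     27     T    16601     16575
    2     1    T    -927.3      48.7       2       4     27     T    16601     16575

corrected-vs-truth Dice = 0.9937
nodule indentation refilled = 1.0
```

Per slice: the segmentation converged (`conv T`) with fitted region means
`c₁ ≈ −927 HU` (air spaces) and `c₂ ≈ +50 HU` (soft tissue); after airway
exclusion two regions (the lungs) remain; four boundary blocks were flagged
defective around the juxtapleural indentation; the correction contour
stabilised after 27 iterations, and the final mask covers the full nodule
footprint while agreeing with the nodule-inclusive ground truth to
Dice 0.994.

The same pipeline runs from the shell:

```sh
lungfield phantom --out scratch/ph --seed 7
lungfield run scratch/ph/phantom.nii --out scratch/run
```

`run` writes pre-/post-correction masks as PNG, per-slice fractal statistics
and contour traces as JSON, and a `run_log.jsonl` with all convergence flags.

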