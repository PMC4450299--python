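"""Synthetic thoracic-CT phantom with ground-truth masks.

The phantom emulates the handful of CT properties the pipeline relies on:
lung parenchyma is radiolucent (well below -500 HU), the chest wall is
soft-tissue density, ribs are osseous and hug the lung margin, the trachea
is an air-filled disk away from any bone (except on slices where a cartilage
ring is drawn), and a juxtapleural nodule is a soft-tissue disk centred on
the lung boundary that carves an indentation out of the lung field.  It does
not attempt anatomically realistic texture, vessels, or deformation.

All geometry is deterministic; only the additive Gaussian noise is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

__all__ = ["PhantomSpec", "TruthMasks", "make_slice", "make_stack"]


@dataclass
class TruthMasks:
    """Ground-truth binary masks for one phantom slice.

    ``lung_with_nodules`` is the smooth lung field including the nodule
    footprint (the boundary-correction target); ``lung_without_nodules`` is
    the lung field with the juxtapleural indentations carved out (what an
    intensity-based segmentation should produce).  The set identity
    ``lung_with_nodules == lung_without_nodules | (nodule disks & lungs)``
    holds by construction.
    """

    lung_with_nodules: np.ndarray
    lung_without_nodules: np.ndarray
    trachea: np.ndarray
    bone: np.ndarray


@dataclass
class PhantomSpec:
    """Parameters of the synthetic CT slice/stack generator.

    HU plateaus default to representative CT values: lung parenchyma
    -800 HU, soft tissue +40 HU, bone +400 HU, air outside the body
    -1000 HU, with 10 HU additive Gaussian noise.  ``nodules`` is a tuple of
    ``((row, col), radius_px)`` entries; ``None`` places a single radius-8
    nodule on the lateral boundary of the left lung.  ``cartilage_slices``
    lists the slice indices carrying a tracheal cartilage ring (``None`` =
    middle slice only), exercising previous-slice exclusion propagation.
    """

    image_size: int = 256
    hu_lung: float = -800.0
    hu_body: float = 40.0
    hu_bone: float = 400.0
    hu_air_outside: float = -1000.0
    noise_sigma: float = 10.0
    nodules: tuple | None = None
    trachea_cartilage: bool = True
    cartilage_slices: tuple | None = None
    n_slices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_lung < -500.0 < self.hu_body < self.hu_bone):
            raise ValueError(
                "phantom HU plateaus must satisfy hu_lung < -500 < hu_body < hu_bone"
            )
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64 px")
        if self.nodules is None:
            # single juxtapleural nodule on the left lung's lateral boundary
            center = (self.lung_centers[0][0], self.lung_centers[0][1] - self.lung_semi[1])
            object.__setattr__(self, "nodules", ((center, 8.0),))
        for (_, _), radius in self.nodules:
            if radius < 3:
                raise ValueError("nodule radius must be >= 3 px")
        if self.cartilage_slices is None:
            slices = (self.n_slices // 2,) if self.trachea_cartilage else ()
            object.__setattr__(self, "cartilage_slices", slices)
        self._check_overlap()

    # --- derived geometry (fractions of a 256-px reference frame) ---------

    @property
    def _s(self) -> float:
        return self.image_size / 256.0

    @property
    def center(self) -> tuple:
        return (self.image_size / 2.0, self.image_size / 2.0)

    @property
    def body_semi(self) -> tuple:
        return (100.0 * self._s, 115.0 * self._s)

    @property
    def lung_semi(self) -> tuple:
        return (70.0 * self._s, 38.0 * self._s)

    @property
    def lung_centers(self) -> tuple:
        r, c = self.center
        off = 50.0 * self._s
        return ((r, c - off), (r, c + off))

    @property
    def trachea_center(self) -> tuple:
        r, c = self.center
        return (r - 59.0 * self._s, c)

    @property
    def trachea_radius(self) -> float:
        return 9.0 * self._s

    def _check_overlap(self) -> None:
        tr, tc = self.trachea_center
        for (nr, nc), rad in self.nodules:
            if math.hypot(nr - tr, nc - tc) < rad + self.trachea_radius + 2:
                raise ValueError("nodule overlaps the trachea; adjust the spec")


def _rib_centers(spec: PhantomSpec) -> list:
    """Rib blob centres: three per lung, offset outward from the lung margin."""
    a, b = spec.lung_semi
    offset = 6.0 * spec._s
    centers = []
    for li, (lr, lc) in enumerate(spec.lung_centers):
        lateral = -1.0 if li == 0 else 1.0
        dirs = [(-0.707, 0.707 * lateral), (0.707, 0.707 * lateral), (1.0, 0.0)]
        for dr, dc in dirs:
            # boundary point of the lung ellipse along (dr, dc)
            t = 1.0 / math.sqrt((dr / a) ** 2 + (dc / b) ** 2)
            norm = math.hypot(dr, dc)
            centers.append((lr + t * dr + offset * dr / norm,
                            lc + t * dc + offset * dc / norm))
    return centers


def make_slice(spec: PhantomSpec, slice_index: int = 0):
    """Render one phantom slice.

    Returns ``(image, truth)`` where ``image`` is the HU-valued float array
    and ``truth`` the :class:`TruthMasks`.  Deterministic for a given
    ``(spec.seed, slice_index)`` pair.
    """
    n = spec.image_size
    shape = (n, n)
    image = np.full(shape, spec.hu_air_outside, dtype=np.float64)

    body = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(*spec.center, *spec.body_semi, shape=shape)
    body[rr, cc] = True
    image[body] = spec.hu_body

    lungs = np.zeros(shape, dtype=bool)
    for lr, lc in spec.lung_centers:
        rr, cc = draw_ellipse(lr, lc, *spec.lung_semi, shape=shape)
        lungs[rr, cc] = True

    nodule_disks = np.zeros(shape, dtype=bool)
    for (nr, nc), rad in spec.nodules:
        rr, cc = draw_disk((nr, nc), rad, shape=shape)
        nodule_disks[rr, cc] = True

    lung_without = lungs & ~nodule_disks
    image[lungs] = spec.hu_lung
    image[nodule_disks] = spec.hu_body  # nodule has soft-tissue density

    trachea = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(spec.trachea_center, spec.trachea_radius, shape=shape)
    trachea[rr, cc] = True
    image[trachea] = spec.hu_lung

    bone = np.zeros(shape, dtype=bool)
    for br, bc in _rib_centers(spec):
        rr, cc = draw_disk((br, bc), 5.0 * spec._s, shape=shape)
        bone[rr, cc] = True
    if slice_index in spec.cartilage_slices:
        ring = np.zeros(shape, dtype=bool)
        rr, cc = draw_disk(spec.trachea_center, spec.trachea_radius + 4.0, shape=shape)
        ring[rr, cc] = True
        rr, cc = draw_disk(spec.trachea_center, spec.trachea_radius + 1.0, shape=shape)
        ring[rr, cc] = False
        bone |= ring
    bone &= ~(lungs | trachea)  # ribs abut but never invade the air spaces
    image[bone] = spec.hu_bone

    if spec.noise_sigma > 0:
        rng = np.random.default_rng((spec.seed, slice_index))
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)

    truth = TruthMasks(
        lung_with_nodules=lungs,
        lung_without_nodules=lung_without,
        trachea=trachea,
        bone=bone,
    )
    return image, truth


def make_stack(spec: PhantomSpec):
    """Render an aligned slice stack.

    Returns ``(images, truths)`` with ``images`` of shape
    ``(n_slices, N, N)``.  By default only the middle slice carries the
    tracheal cartilage ring, so the trachea on that slice survives the
    osseous-neighbourhood test and must be removed by previous-slice
    propagation.
    """
    if spec.n_slices < 3:
        raise ValueError("a phantom stack needs n_slices >= 3")
    images = []
    truths = []
    for idx in range(spec.n_slices):
        img, truth = make_slice(spec, idx)
        images.append(img)
        truths.append(truth)
    return np.stack(images), truths
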