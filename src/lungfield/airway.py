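"""Rule-based central-airway exclusion.

The trachea and main bronchi are air-filled, so intensity-based segmentation
keeps them.  Two anatomical rules remove them: (1) the lung fields are hugged
by ribs, while the central airway sits away from any osseous tissue, so a
segmented component whose dilated neighbourhood ring contains no bone-density
pixels is discarded; (2) where a tracheal cartilage ring mimics bone on a
slice, the component is still discarded if its footprint was (mostly)
excluded on the previous slice of the stack, since the cartilage does not
persist along z and organ positions barely move between adjacent slices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.segmentation import clear_border

__all__ = [
    "AirwayParams",
    "RegionLabeling",
    "label_regions",
    "has_osseous_neighborhood",
    "exclude_airway_slice",
    "propagate_exclusion",
    "clear_background",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class AirwayParams:
    """Controls of the osseous-neighbourhood test and slice propagation.

    A component is kept when the ring obtained by dilating it by
    ``dilation_radius`` pixels (minus the component itself) contains at least
    ``min_bone_pixels`` pixels above ``bone_hu_threshold``.  From the second
    slice on, a component is dropped when more than ``overlap_fraction`` of
    its footprint was excluded on the previous processed slice.
    """

    dilation_radius: int = 8
    bone_hu_threshold: float = 200.0
    min_bone_pixels: int = 20
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.dilation_radius < 1:
            raise ValueError("dilation_radius must be >= 1")
        if not 0.0 < self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in (0, 1]")


@dataclass
class RegionLabeling:
    """8-connected components in deterministic raster order of first pixel."""

    labels: np.ndarray
    region_ids: list
    areas: dict


def label_regions(mask: np.ndarray) -> RegionLabeling:
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return RegionLabeling(labels=raw, region_ids=[], areas={})
    # relabel in raster order of each region's first pixel
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    np.minimum.at(first, flat[idx], idx)
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order] = np.arange(1, n + 1)
    labels = remap[raw]
    ids = list(range(1, n + 1))
    areas = {i: int((labels == i).sum()) for i in ids}
    return RegionLabeling(labels=labels, region_ids=ids, areas=areas)


def has_osseous_neighborhood(region_mask: np.ndarray, image: np.ndarray,
                             params: AirwayParams | None = None) -> bool:
    """True iff the dilated ring around the region contains enough bone pixels."""
    params = params or AirwayParams()
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("region is empty")
    ring = ndimage.binary_dilation(region, structure=disk(params.dilation_radius)) & ~region
    n_bone = int(np.count_nonzero(np.asarray(image)[ring] > params.bone_hu_threshold))
    return n_bone >= params.min_bone_pixels


def exclude_airway_slice(mask: np.ndarray, image: np.ndarray,
                         params: AirwayParams | None = None) -> np.ndarray:
    """Remove every component that fails the osseous-neighbourhood test."""
    params = params or AirwayParams()
    labeling = label_regions(mask)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for rid in labeling.region_ids:
        region = labeling.labels == rid
        if has_osseous_neighborhood(region, image, params):
            out |= region
    if labeling.region_ids and not out.any():
        warnings.warn("airway exclusion removed every region; "
                      "check bone threshold/dilation radius", stacklevel=2)
    return out


def propagate_exclusion(mask_stack, raw_stack,
                        params: AirwayParams | None = None) -> list:
    """Forward pass removing components excluded at the same location before.

    ``raw_stack`` holds the masks before slice-wise exclusion, ``mask_stack``
    the masks after it.  From the second slice on, a component of the current
    mask is dropped when the fraction of its footprint that was excluded on
    the previous processed slice (present in raw, absent in processed)
    exceeds ``overlap_fraction``.
    """
    params = params or AirwayParams()
    if len(mask_stack) != len(raw_stack):
        raise ValueError("mask_stack and raw_stack must have the same length")
    processed: list = []
    for t, mask in enumerate(mask_stack):
        mask = np.asarray(mask, dtype=bool)
        if t == 0:
            processed.append(mask.copy())
            continue
        excluded_prev = np.asarray(raw_stack[t - 1], dtype=bool) & ~processed[t - 1]
        labeling = label_regions(mask)
        out = np.zeros_like(mask)
        for rid in labeling.region_ids:
            region = labeling.labels == rid
            frac = np.count_nonzero(region & excluded_prev) / np.count_nonzero(region)
            if frac <= params.overlap_fraction:
                out |= region
        processed.append(out)
    return processed


def clear_background(mask: np.ndarray) -> np.ndarray:
    """Drop foreground components touching the frame border (outside-body air)."""
    return clear_border(np.asarray(mask, dtype=bool))
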