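"""Model/Results facade driving the full extraction+correction pipeline.

`LungFieldModel` wraps a CT slice stack (or a single slice) together with a
`PipelineConfig`; `fit()` runs, per slice, the convex segmentation, border
clearing, hole filling and airway exclusion, then stack-wise exclusion
propagation, per-slice fractal defect detection and geometric-contour
boundary correction, and returns a `LungFieldResults` carrying every
intermediate mask, the diagnostics, and a text `summary()`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as lfio
from .airway import AirwayParams, clear_background, exclude_airway_slice, propagate_exclusion
from .correction import CorrectionParams, correct_boundary
from .edges import EdgeParams
from .fractal import count_subregions, detect_defective_blocks
from .phantom import PhantomSpec, make_slice, make_stack
from .segmentation import SegmentationParams, fill_holes, segment

__all__ = ["PipelineConfig", "LungFieldModel", "LungFieldResults", "dice_coefficient"]

STAGES = ("segment", "airway", "detect", "correct")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / float(denom)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, JSON-serialisable round trip."""

    edge: EdgeParams = field(default_factory=EdgeParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    airway: AirwayParams = field(default_factory=AirwayParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    defect_multiplier: float = 1.0
    stages: tuple = STAGES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            edge=EdgeParams(**d.get("edge", {})),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            airway=AirwayParams(**d.get("airway", {})),
            correction=CorrectionParams(**d.get("correction", {})),
            defect_multiplier=d.get("defect_multiplier", 1.0),
            stages=tuple(d.get("stages", STAGES)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SliceReport:
    """Per-slice diagnostics gathered while fitting."""

    index: int
    seg_iters: int = 0
    seg_converged: bool = False
    c1: float = float("nan")
    c2: float = float("nan")
    n_subregions: int = 0
    n_defective_blocks: int = 0
    t_f: float = float("nan")
    corr_iters: int = 0
    corr_converged: bool = False
    area_pre: int = 0
    area_post: int = 0
    error: str | None = None


class LungFieldResults:
    """Fitted masks, diagnostics, and reporting helpers."""

    def __init__(self, config: PipelineConfig, images: np.ndarray):
        self.config = config
        self.images = images
        n = images.shape[0]
        self.masks_raw = [None] * n          # cleared + hole-filled segmentation
        self.masks_airway = [None] * n       # after exclusion (+ propagation)
        self.masks_corrected = [None] * n
        self.levelsets = [None] * n
        self.fractal_stats = [None] * n
        self.block_grids = [None] * n
        self.correction_traces = [None] * n
        self.reports = [SliceReport(index=i) for i in range(n)]

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]

    def final_masks(self) -> list:
        """Most processed mask available per slice."""
        out = []
        for i in range(self.n_slices):
            for seq in (self.masks_corrected, self.masks_airway, self.masks_raw):
                if seq[i] is not None:
                    out.append(seq[i])
                    break
            else:
                out.append(None)
        return out

    def summary(self) -> str:
        hdr = (f"{'slice':>5} {'segit':>5} {'conv':>4} {'c1':>9} {'c2':>9} "
               f"{'regions':>7} {'defects':>7} {'corrit':>6} {'cconv':>5} "
               f"{'area_pre':>8} {'area_post':>9}")
        lines = ["Lung-field extraction results", "=" * len(hdr), hdr, "-" * len(hdr)]
        for r in self.reports:
            lines.append(
                f"{r.index:>5} {r.seg_iters:>5} {str(r.seg_converged)[0]:>4} "
                f"{r.c1:>9.1f} {r.c2:>9.1f} {r.n_subregions:>7} "
                f"{r.n_defective_blocks:>7} {r.corr_iters:>6} "
                f"{str(r.corr_converged)[0]:>5} {r.area_pre:>8} {r.area_post:>9}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write masks (pre/post correction), fractal stats, traces and a run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.save(outdir / "config.json")
        log = []
        for i in range(self.n_slices):
            if self.masks_airway[i] is not None:
                lfio.write_mask_png(self.masks_airway[i], outdir / f"mask_pre_{i:03d}.png")
            if self.masks_corrected[i] is not None:
                lfio.write_mask_png(self.masks_corrected[i], outdir / f"mask_post_{i:03d}.png")
            if self.fractal_stats[i] is not None:
                self.fractal_stats[i].to_json(outdir / f"fractal_{i:03d}.json")
            if self.correction_traces[i] is not None:
                with open(outdir / f"trace_{i:03d}.json", "w") as fh:
                    json.dump(self.correction_traces[i], fh)
            log.append(dataclasses.asdict(self.reports[i]))
        with open(outdir / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def plot_slice(self, index: int = 0):
        """Overlay of the image, pre-correction and corrected contours."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(self.images[index], cmap="gray")
        for mask, color, label in (
            (self.masks_airway[index], "tab:orange", "pre-correction"),
            (self.masks_corrected[index], "tab:red", "corrected"),
        ):
            if mask is not None:
                ax.contour(mask.astype(float), levels=[0.5], colors=color)
                ax.plot([], [], color=color, label=label)
        ax.legend(loc="lower right")
        ax.set_axis_off()
        return fig


class LungFieldModel:
    """Lung-field extraction model over a CT slice stack.

    Parameters
    ----------
    images : ndarray
        HU-valued array of shape (H, W) or (S, H, W).
    config : PipelineConfig, optional
        Pipeline parameters; defaults reproduce the reference settings.
    """

    def __init__(self, images: np.ndarray, config: PipelineConfig | None = None):
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None, ...]
        if images.ndim != 3:
            raise ValueError("images must be (H, W) or (S, H, W)")
        self.images = images
        self.config = config or PipelineConfig()
        self.ground_truth = None  # populated by from_phantom

    @classmethod
    def from_phantom(cls, spec: PhantomSpec | None = None,
                     config: PipelineConfig | None = None) -> "LungFieldModel":
        spec = spec or PhantomSpec()
        if spec.n_slices >= 3:
            images, truths = make_stack(spec)
        else:
            img, truth = make_slice(spec, 0)
            images, truths = img[None, ...], [truth]
        model = cls(images, config)
        model.ground_truth = truths
        return model

    @classmethod
    def from_file(cls, path, fmt: str | None = None, slope: float | None = None,
                  intercept: float | None = None,
                  config: PipelineConfig | None = None) -> "LungFieldModel":
        return cls(lfio.read_ct(path, fmt, slope, intercept), config)

    def fit(self, stages: tuple | None = None) -> LungFieldResults:
        """Run the pipeline through the requested stages (prefix of
        segment -> airway -> detect -> correct)."""
        stages = tuple(stages or self.config.stages)
        res = LungFieldResults(self.config, self.images)
        cfg = self.config

        for i in range(res.n_slices):
            img = self.images[i]
            seg = segment(img, cfg.segmentation, cfg.edge)
            rep = res.reports[i]
            rep.seg_iters = seg.n_iters
            rep.seg_converged = seg.converged
            rep.c1, rep.c2 = seg.c1, seg.c2
            res.levelsets[i] = seg.phi
            res.masks_raw[i] = fill_holes(clear_background(seg.mask))

        if "airway" in stages:
            excluded = []
            for i in range(res.n_slices):
                excluded.append(
                    exclude_airway_slice(res.masks_raw[i], self.images[i], cfg.airway)
                )
            res.masks_airway = propagate_exclusion(excluded, res.masks_raw, cfg.airway)
            for i in range(res.n_slices):
                rep = res.reports[i]
                rep.n_subregions = count_subregions(res.masks_airway[i])
                rep.area_pre = int(np.count_nonzero(res.masks_airway[i]))

        if "detect" in stages and "airway" in stages:
            for i in range(res.n_slices):
                rep = res.reports[i]
                try:
                    stats, grid = detect_defective_blocks(
                        res.masks_airway[i], multiplier=cfg.defect_multiplier
                    )
                except ValueError as exc:
                    rep.error = f"defect detection: {exc}"
                    continue
                res.fractal_stats[i] = stats
                res.block_grids[i] = grid
                rep.n_defective_blocks = int(stats.is_defective.sum())
                rep.t_f = stats.t_f

        if "correct" in stages and "detect" in stages:
            for i in range(res.n_slices):
                if res.fractal_stats[i] is None:
                    continue
                mask, trace = correct_boundary(
                    res.masks_airway[i], res.fractal_stats[i],
                    res.block_grids[i], cfg.correction,
                )
                res.masks_corrected[i] = mask
                res.correction_traces[i] = trace
                rep = res.reports[i]
                rep.corr_iters = trace["n_iters"]
                rep.corr_converged = trace["converged"]
                rep.area_post = int(np.count_nonzero(mask))
        return res
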