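"""Reproducible quantification pipeline: mask → band → detect → classify → count.

A :class:`RunConfig` captures every tunable of the pipeline; a config
plus a seed reproduces a run bit-identically.  The stages are exposed
both as one library call per image (:func:`quantify_image`) and as a
full synthetic-pair experiment (:func:`run_quantification`) used by the
command-line interface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify as cls
from . import detection as det
from . import regions as reg
from . import survival as surv
from .synthetic import SyntheticSpec, generate_pair, truth_to_frame

__all__ = ["RunConfig", "ImageResult", "quantify_image", "run_quantification",
           "read_calibrated_tiff", "write_calibrated_tiff"]

log = logging.getLogger("rgcquant")


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters for one run; YAML-serializable."""

    pixel_size_um: float = 0.46
    edge_offset_um: float = reg.DEFAULT_EDGE_OFFSET_UM
    thickness_um: float = reg.DEFAULT_THICKNESS_UM
    frst: det.FRSTParams = field(default_factory=det.FRSTParams)
    ring_width_um: float = 2.0
    bundle_min_area_um2: float = 500.0
    bundle_min_elongation: float = 1.0
    bundle_opening_radius_um: float = 2.5
    otsu_n_bins: int = 256
    min_separation_um: float = 8.0
    score_threshold: float = 0.10
    closing_radius_um: float = 5.0
    normalization: str = "density"       # count | density | auto
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "edge_offset_um", "thickness_um",
                     "ring_width_um", "bundle_min_area_um2",
                     "bundle_min_elongation", "min_separation_um",
                     "closing_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.otsu_n_bins < 2:
            raise ValueError("otsu_n_bins must be >= 2")
        if self.normalization not in ("auto", "count", "density"):
            raise ValueError("normalization must be auto, count or density")
        if isinstance(self.frst, dict):
            object.__setattr__(self, "frst", det.FRSTParams(**self.frst))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["frst"]["radii_um"] = list(d["frst"]["radii_um"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "frst" in d and isinstance(d["frst"], dict):
            d["frst"]["radii_um"] = tuple(d["frst"].get("radii_um", ()))
            d["frst"] = det.FRSTParams(**d["frst"])
        return cls_(**d)


@dataclass(frozen=True)
class ImageResult:
    """Everything the pipeline produced for one image."""

    tissue_mask: np.ndarray = field(repr=False)
    band: reg.SamplingBand = field(repr=False)
    detections: list[det.NucleusDetection] = field(repr=False)
    calls: list[cls.CellCall] = field(repr=False)
    count: surv.RetinaCount = None  # type: ignore[assignment]
    tuj1_threshold: float = float("nan")

    def detections_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"id": i, "row": d.center_row_px, "col": d.center_col_px,
                 "radius_um": d.radius_um, "score": d.symmetry_score}
                for i, d in enumerate(self.detections)
            ],
            columns=["id", "row", "col", "radius_um", "score"],
        )

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for d, c in zip(self.detections, self.calls):
            rows.append({
                "detection_id": c.detection_id,
                "row": d.center_row_px,
                "col": d.center_col_px,
                "ring_fraction": c.ring_positive_fraction,
                "n_pixels": c.n_ring_pixels_considered,
                "excluded_by_bundle": c.excluded_by_bundle,
                "is_rgc_positive": c.is_rgc_positive,
            })
        return pd.DataFrame(rows, columns=[
            "detection_id", "row", "col", "ring_fraction", "n_pixels",
            "excluded_by_bundle", "is_rgc_positive"])


def quantify_image(
    image: reg.CalibratedImage,
    config: RunConfig,
    specimen_id: str = "specimen",
    condition: str = "crushed",
    tissue_mask: np.ndarray | None = None,
) -> ImageResult:
    """Run every per-image stage and return all intermediates.

    ``tissue_mask`` may be supplied (e.g. the generator's exact mask);
    by default it is recovered from the image.
    """
    if tissue_mask is None:
        tissue_mask = reg.compute_tissue_mask(
            image, config.closing_radius_um, config.otsu_n_bins
        )
    band = reg.compute_sampling_band(
        tissue_mask, image.pixel_size_um,
        config.edge_offset_um, config.thickness_um,
    )
    sym = det.radial_symmetry_transform(
        image.synuclein, config.frst, image.pixel_size_um
    )
    detections = det.detect_nuclei(
        sym, band, config.min_separation_um, config.score_threshold
    )
    thr = cls.otsu_threshold(image.tuj1, band.mask, config.otsu_n_bins)
    tuj1_binary = image.tuj1 > thr
    bundles = cls.detect_axon_bundles(
        tuj1_binary & tissue_mask, image.pixel_size_um,
        config.bundle_min_area_um2, config.bundle_min_elongation,
        config.ring_width_um, config.bundle_opening_radius_um,
    )
    calls = cls.classify_cells(
        detections, tuj1_binary, bundles, config.ring_width_um,
        image.pixel_size_um,
    )
    count = surv.summarize_retina(
        calls, band, image.pixel_size_um, specimen_id, condition,
        bundle_mask=bundles.mask,
    )
    log.info(
        "%s/%s: %d detections, %d double-positive, band %.0f um^2",
        specimen_id, condition, count.n_detected, count.n_double_positive,
        count.band_area_um2,
    )
    return ImageResult(tissue_mask, band, detections, calls, count, float(thr))


def run_quantification(
    config: RunConfig,
    outdir: str | Path,
    synthetic_spec: SyntheticSpec | None = None,
    input_tiffs: dict[str, str | Path] | None = None,
    save_intermediates: bool = False,
) -> dict:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Either a synthetic spec (a crushed/uncrushed pair is generated) or a
    mapping ``{"crushed": path, "uncrushed": path}`` of two-channel
    TIFFs (channel order: synuclein, TUJ-1) must be given.  Returns the
    JSON-serializable run summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": json.loads(json.dumps(
        dataclasses.asdict(config), default=list))}

    images: dict[str, reg.CalibratedImage] = {}
    masks: dict[str, np.ndarray | None] = {}
    if synthetic_spec is not None:
        spec = dataclasses.replace(synthetic_spec, seed=config.seed)
        (img_c, truth_c, mask_c), (img_u, truth_u, mask_u) = generate_pair(spec)
        images = {"crushed": img_c, "uncrushed": img_u}
        masks = {"crushed": mask_c, "uncrushed": mask_u}
        truth_to_frame(truth_c).to_csv(outdir / "truth_crushed.csv", index=False)
        truth_to_frame(truth_u).to_csv(outdir / "truth_uncrushed.csv", index=False)
    elif input_tiffs:
        for cond, path in input_tiffs.items():
            images[cond] = read_calibrated_tiff(path, config.pixel_size_um)
            masks[cond] = None
    else:
        raise ValueError("need either a synthetic spec or input TIFF paths")

    counts = {}
    for cond, image in images.items():
        res = quantify_image(image, config, "animal", cond, masks[cond])
        res.detections_frame().to_csv(
            outdir / f"detections_{cond}.csv", index=False)
        res.calls_frame().to_csv(outdir / f"calls_{cond}.csv", index=False)
        if save_intermediates:
            tifffile.imwrite(outdir / f"tissue_mask_{cond}.tif",
                             res.tissue_mask.astype(np.uint8) * 255)
            tifffile.imwrite(outdir / f"band_{cond}.tif",
                             res.band.mask.astype(np.uint8) * 255)
        counts[cond] = res.count
        summary[cond] = {
            "n_detected": res.count.n_detected,
            "n_double_positive": res.count.n_double_positive,
            "band_area_um2": res.count.band_area_um2,
            "density_per_mm2": res.count.density_per_mm2,
            "tuj1_threshold": res.tuj1_threshold,
        }

    if {"crushed", "uncrushed"} <= counts.keys():
        result = surv.normalize_survival(
            counts["crushed"], counts["uncrushed"], "animal",
            config.normalization,
        )
        summary["survival_percent"] = result.survival_percent
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    pd.DataFrame([
        {"specimen_id": c.specimen_id, "condition": c.condition,
         "n_double_positive": c.n_double_positive,
         "n_detected": c.n_detected, "band_area_um2": c.band_area_um2,
         "density_per_mm2": c.density_per_mm2}
        for c in counts.values()
    ]).to_csv(outdir / "counts.csv", index=False)
    return summary


def read_calibrated_tiff(path: str | Path, pixel_size_um: float) -> reg.CalibratedImage:
    """Read a 2-channel TIFF (synuclein, TUJ-1) into a CalibratedImage."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 3 or 2 not in arr.shape[:1] + arr.shape[-1:]:
        raise ValueError(
            f"{path}: expected a 2-channel image, got shape {arr.shape}")
    if arr.shape[0] != 2:                 # channels-last layout
        arr = np.moveaxis(arr, -1, 0)
    return reg.CalibratedImage(arr[0], arr[1], pixel_size_um)


def write_calibrated_tiff(path: str | Path, image: reg.CalibratedImage) -> None:
    """Write both channels as a 2-page 16-bit TIFF."""
    stack = np.stack([image.synuclein, image.tuj1])
    tifffile.imwrite(str(path), np.clip(stack, 0, 65535).astype(np.uint16))
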