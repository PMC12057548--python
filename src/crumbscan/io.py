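"""File I/O, configuration and the image-analysis pipeline driver.

The pipeline mirrors the standard crumb-grain workflow: read the photograph,
convert to 8-bit gray, build the histogram, choose a threshold per method,
binarize (pores dark), despeckle, label and measure particles, then
summarize with the fractal descriptors. ``run_pipeline`` applies it to a
batch of images and returns one tidy row per image x method.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import fractal, particles as pa, thresholding as th
from .errors import CrumbscanError, ParameterError

__all__ = [
    "AnalysisConfig",
    "read_image",
    "write_image",
    "write_ground_truth",
    "write_profile_csv",
    "run_pipeline",
    "summary_to_row",
]

log = logging.getLogger("crumbscan")

#: BT.601 luma weights for RGB -> gray conversion
_LUMA = (0.299, 0.587, 0.114)

SUMMARY_COLUMNS = [
    "image",
    "method",
    "threshold",
    "cell_count",
    "total_area_mm2",
    "average_cell_size_mm2",
    "pct_area",
    "min_cell_area_mm2",
    "max_cell_area_mm2",
    "mean_cell_periphery_mm",
    "dfp_mean",
    "dft",
    "error",
]


@dataclass
class AnalysisConfig:
    """Knobs of the image pipeline.

    ``field_mm`` is the physical width of the analyzed square field (the
    pixel scale is ``field_mm / image width``); ``min_area_mm2`` drops
    sub-resolution specks; ``dft_method`` selects the texture-fractal
    variant.
    """

    methods: tuple[str, ...] = th.THRESHOLD_METHODS
    polarity: str = "dark"
    connectivity: int = 8
    min_area_mm2: float = pa.DEFAULT_MIN_AREA_MM2
    field_mm: float = 30.0
    noise_removal: bool = True
    dft_method: str = "size_distribution"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.methods:
            raise ParameterError("methods must be non-empty")
        unknown = set(self.methods) - set(th.THRESHOLD_METHODS)
        if unknown:
            raise ParameterError(f"unknown methods: {sorted(unknown)}")
        if not self.field_mm > 0:
            raise ParameterError("field_mm must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["methods"] = list(data["methods"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_image(path: str | Path, field_mm: float = 30.0) -> th.GrayImage:
    """Read a PNG/TIFF/JPEG photograph as an 8-bit gray image.

    RGB inputs are converted with luma weights 0.299/0.587/0.114 and rounded
    to integers. The pixel scale is ``field_mm / width_px``.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("L",):
                px = np.asarray(im, dtype=np.uint8)
            elif im.mode in ("RGB", "RGBA"):
                arr = np.asarray(im.convert("RGB"), dtype=np.float64)
                px = np.rint(arr @ np.array(_LUMA)).astype(np.uint8)
            elif im.mode in ("I", "I;16", "F", "P", "LA"):
                px = np.asarray(im.convert("L"), dtype=np.uint8)
            else:
                raise OSError(f"unsupported image mode {im.mode!r} in {path}")
    except FileNotFoundError as exc:
        raise OSError(f"cannot read image file: {path}") from exc
    return th.GrayImage(pixels=px, scale_mm_per_px=field_mm / px.shape[1])


def write_image(image: th.GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF."""
    Image.fromarray(image.pixels, mode="L").save(path)


def write_ground_truth(truth, path: str | Path) -> None:
    """JSON sidecar with the exact pore statistics (mask stored as run lengths)."""
    payload = {
        "true_count": truth.true_count,
        "true_total_area_mm2": truth.true_total_area_mm2,
        "true_mean_area_mm2": truth.true_mean_area_mm2,
        "scale_mm_per_px": truth.pore_mask.scale_mm_per_px,
        "shape": list(truth.pore_mask.bits.shape),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def write_profile_csv(profile, path: str | Path) -> None:
    """Digestion curve as CSV with columns time_min, glucose or percent digested."""
    if profile.curve is None:
        raise ParameterError("profile has no curve to write")
    df = pd.DataFrame(profile.curve, columns=["time_min", "pct_starch_digested"])
    df.to_csv(path, index=False)


def analyze_image(
    image: th.GrayImage, config: AnalysisConfig, name: str = "image"
) -> list[dict]:
    """Run every configured thresholder on one image; one row per method.

    Per-method failures (e.g. a blank image raising NoSeparation) are logged
    and recorded in the row's ``error`` column; they never abort the batch.
    """
    rows: list[dict] = []
    hist = None
    for method in config.methods:
        row = {c: None for c in SUMMARY_COLUMNS}
        row["image"] = name
        row["method"] = method
        try:
            if hist is None:
                hist = th.build_histogram(image)
            result = th.compute_threshold(hist, method)
            mask = th.binarize(image, result.T, polarity=config.polarity)
            if config.noise_removal:
                mask = pa.remove_noise(mask)
            parts = pa.label_particles(mask, connectivity=config.connectivity)
            parts = pa.measure_particles(
                parts, image.scale_mm_per_px, config.min_area_mm2
            )
            fractal.attach_dfp(parts)
            dft = None
            try:
                source = mask if config.dft_method == "box_counting" else parts
                dft = fractal.texture_fractal_dimension(
                    source, method=config.dft_method
                ).dft
            except CrumbscanError:
                pass  # too few scales: DFt stays undefined
            field_area = config.field_mm**2
            summary = pa.summarize_pores(parts, field_area_mm2=field_area, dft=dft)
            row.update(
                threshold=result.T,
                cell_count=summary.cell_count,
                total_area_mm2=summary.total_area_mm2,
                average_cell_size_mm2=summary.average_cell_size_mm2,
                pct_area=summary.pct_area,
                min_cell_area_mm2=summary.min_cell_area_mm2,
                max_cell_area_mm2=summary.max_cell_area_mm2,
                mean_cell_periphery_mm=summary.mean_cell_periphery_mm,
                dfp_mean=summary.dfp_mean,
                dft=summary.dft,
            )
            log.info("%s/%s: T=%d, %d cells", name, method, result.T, summary.cell_count)
        except CrumbscanError as exc:
            row["error"] = f"{type(exc).__name__}: {exc}"
            log.warning("%s/%s failed: %s", name, method, exc)
        rows.append(row)
    return rows


def run_pipeline(
    image_paths: list[str | Path], config: AnalysisConfig
) -> pd.DataFrame:
    """Batch the full pipeline over images; one summary row per image x method."""
    if not image_paths:
        raise ParameterError("need at least one image")
    rows: list[dict] = []
    for path in image_paths:
        try:
            image = read_image(path, field_mm=config.field_mm)
        except OSError as exc:
            log.warning("skipping %s: %s", path, exc)
            for method in config.methods:
                row = {c: None for c in SUMMARY_COLUMNS}
                row.update(image=str(path), method=method, error=str(exc))
                rows.append(row)
            continue
        rows.extend(analyze_image(image, config, name=str(path)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def summary_to_row(summary: pa.PoreSummary) -> dict:
    """PoreSummary as a plain dict (for JSON/CSV export)."""
    return asdict(summary)


def particles_to_frame(particles: list[pa.Particle]) -> pd.DataFrame:
    """Measured particles as a tidy per-cell table (CSV-ready)."""
    return pd.DataFrame(
        {
            "id": p.id,
            "pixel_count": p.pixel_count,
            "area_mm2": p.area_mm2,
            "perimeter_mm": p.perimeter_mm,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "touches_border": p.touches_border,
            "dfp": p.dfp,
        }
        for p in particles
    )
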