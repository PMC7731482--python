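"""ROI- and patient-level F/B quantification.

The forward/backward scattering ratio of a region of interest is computed by
background-subtracting the F and B intensity images, dividing them pixelwise
into a ratio image, and averaging the ratio over the pixels of a binary
collagen mask. Session-to-session instrument drift is removed by dividing each
ROI's mean F/B by the F/B of a fluorescein (FITC) reference solution imaged in
the same session. The three ROIs acquired per region type are averaged into a
single per-patient, per-region value, and survival analyses work with its
natural log (ln F/B).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .masking import BinaryMask

__all__ = [
    "FBResult",
    "CalibrationRecord",
    "subtract_background",
    "fb_image",
    "roi_mean_fb",
    "calibrate",
    "aggregate_region",
    "render_heatmap",
]

REGION_TYPES = ("tumor_bulk", "tumor_stroma_interface", "far")
METHODS = ("manual", "otsu", "adaptive")


@dataclass(frozen=True)
class FBResult:
    """Masked mean F/B of one ROI."""

    roi_id: str
    region_type: str
    method: str
    mean_fb: float
    n_pixels: int
    calibrated: bool
    session_id: str

    def __post_init__(self) -> None:
        if self.n_pixels > 0 and not self.mean_fb > 0:
            raise ValueError("mean_fb must be positive when pixels were measured")


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-session FITC reference F/B."""

    session_id: str
    fitc_fb: float

    def __post_init__(self) -> None:
        if not self.fitc_fb > 0:
            raise ValueError("fitc_fb must be positive")


def subtract_background(image: np.ndarray, background: np.ndarray | float) -> np.ndarray:
    """Subtract a background frame or scalar offset, floored at zero."""
    img = np.asarray(image, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim not in (0, img.ndim):
        raise ValueError("background must be a scalar or match the image shape")
    if bg.ndim == img.ndim and bg.shape != img.shape:
        raise ValueError(f"background shape {bg.shape} != image shape {img.shape}")
    return np.maximum(img - bg, 0.0)


def fb_image(f: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise F/B ratio; pixels with b == 0 become NaN and are excluded downstream."""
    f = np.asarray(f, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if f.shape != b.shape:
        raise ValueError(f"shape mismatch: F {f.shape} vs B {b.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, f / np.where(b > 0, b, 1.0), np.nan)
    return ratio


def roi_mean_fb(
    ratio_image: np.ndarray,
    mask: BinaryMask,
    roi_id: str = "roi",
    region_type: str = "tumor_bulk",
    session_id: str = "session",
) -> FBResult:
    """Mean of the ratio image over mask=1 pixels with a finite ratio."""
    ratio = np.asarray(ratio_image, dtype=np.float64)
    if ratio.shape != mask.values.shape:
        raise ValueError("ratio image and mask shapes differ")
    usable = (mask.values == 1) & np.isfinite(ratio)
    n = int(usable.sum())
    if n == 0:
        raise ValueError(f"ROI {roi_id!r}: mask selects no usable (finite-ratio) pixels")
    return FBResult(
        roi_id=roi_id,
        region_type=region_type,
        method=mask.method,
        mean_fb=float(ratio[usable].mean()),
        n_pixels=n,
        calibrated=False,
        session_id=session_id,
    )


def calibrate(result: FBResult, cal: CalibrationRecord) -> FBResult:
    """Divide an ROI's mean F/B by the session's FITC reference F/B."""
    if result.session_id != cal.session_id:
        raise ValueError(
            f"session mismatch: result {result.session_id!r} vs calibration {cal.session_id!r}"
        )
    return replace(result, mean_fb=result.mean_fb / cal.fitc_fb, calibrated=True)


def aggregate_region(results: list[FBResult]) -> float:
    """Unweighted mean F/B across one patient+region+method's ROIs (typically 3)."""
    if not results:
        raise ValueError("no ROI results to aggregate")
    regions = {r.region_type for r in results}
    methods = {r.method for r in results}
    if len(regions) > 1 or len(methods) > 1:
        raise ValueError(
            f"heterogeneous aggregation: regions={sorted(regions)} methods={sorted(methods)}"
        )
    if not all(r.calibrated for r in results):
        raise ValueError("all ROI results must be calibrated before aggregation")
    return float(np.mean([r.mean_fb for r in results]))


def render_heatmap(
    ratio_image: np.ndarray,
    mask: BinaryMask,
    path: str | Path | None = None,
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """False-color F/B heatmap: masked-out pixels dark, low F/B blue, high F/B yellow.

    Returns the RGB array (uint8); writes a PNG when ``path`` is given.
    """
    import matplotlib

    ratio = np.asarray(ratio_image, dtype=np.float64)
    if ratio.shape != mask.values.shape:
        raise ValueError("ratio image and mask shapes differ")
    shown = np.where((mask.values == 1) & np.isfinite(ratio), ratio, np.nan)
    finite = shown[np.isfinite(shown)]
    lo = vmin if vmin is not None else (float(finite.min()) if finite.size else 0.0)
    hi = vmax if vmax is not None else (float(finite.max()) if finite.size else 1.0)
    if hi <= lo:
        hi = lo + 1.0
    cmap = matplotlib.colormaps["viridis"].copy()
    cmap.set_bad(color=(0.05, 0.05, 0.08))
    rgba = cmap((shown - lo) / (hi - lo))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    if path is not None:
        from PIL import Image

        Image.fromarray(rgb).save(Path(path), format="PNG")
    return rgb
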