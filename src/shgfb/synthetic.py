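"""Synthetic SHG image pairs and patient cohorts with known ground truth.

The image phantoms emulate the qualitative features of SHG micrographs of
tumor collagen: bright curvilinear fiber strokes on a dark background, a
per-pixel true forward/backward ratio, an additive detector background offset,
and shot-like noise whose standard deviation grows with the square root of the
signal. The cohort generator draws correlated per-region ln F/B values and a
21-gene recurrence score (S-ODX) per patient and plants a proportional-hazards
survival structure on top, so that every downstream stage — masking,
quantification, Kaplan-Meier / Cox analysis, and the risk tree — can be tested
end-to-end against known truth without any external data.

All generators take an explicit integer seed and are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .quant import CalibrationRecord

__all__ = [
    "ImageTruth",
    "ImagePair",
    "PhantomParams",
    "CohortTruth",
    "TreeCohortTruth",
    "generate_image_pair",
    "generate_cohort",
    "generate_tree_cohort",
    "generate_calibration_record",
    "write_image_pair",
]


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth accompanying a synthetic image pair."""

    true_fb_map: np.ndarray  # per-pixel F/B ratio, strictly positive
    fiber_mask_truth: np.ndarray  # boolean; True inside fibers
    background_offset: float
    noise_scale: float


@dataclass(frozen=True)
class ImagePair:
    """Co-registered forward (F) and backward (B) intensity images of one ROI."""

    f_image: np.ndarray
    b_image: np.ndarray
    roi_id: str
    region_type: str
    session_id: str

    def __post_init__(self) -> None:
        if self.f_image.shape != self.b_image.shape:
            raise ValueError("F and B images must share one shape")
        if (np.asarray(self.f_image) < 0).any() or (np.asarray(self.b_image) < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class PhantomParams:
    """Settings for fiber-phantom generation.

    Fibers are random-walk polylines blurred to a Gaussian cross-profile.
    ``fb_mean`` sets the average planted F/B; ``fb_log_sigma`` > 0 adds smooth
    spatial variation of the ratio (log-normal field); ``constant_fb`` forces
    a spatially constant ratio, overriding both.
    """

    n_fibers: int = 25
    fiber_width: float = 4.0  # px, FWHM-like scale of the Gaussian profile
    peak_intensity: float = 2000.0
    background_offset: float = 50.0
    noise_scale: float = 3.0
    fb_mean: float = 15.0
    fb_log_sigma: float = 0.25
    constant_fb: float | None = None
    heterogeneity: float = 0.3  # slow multiplicative intensity modulation depth

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.background_offset < 0:
            raise ValueError("background_offset must be non-negative")
        if self.constant_fb is not None and not self.constant_fb > 0:
            raise ValueError("constant_fb must be positive")
        if not self.fb_mean > 0:
            raise ValueError("fb_mean must be positive")


def _fiber_intensity(
    shape: tuple[int, int], params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    """Render random-walk fiber strokes, Gaussian-blurred to finite width."""
    h, w = shape
    canvas = np.zeros(shape, dtype=np.float64)
    for _ in range(params.n_fibers):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.4, 1.2) * min(h, w))
        for _ in range(length):
            iy, ix = int(y), int(x)
            if 0 <= iy < h and 0 <= ix < w:
                canvas[iy, ix] += 1.0
            theta += rng.normal(0, 0.12)  # angular diffusion -> curvilinear
            y += np.sin(theta)
            x += np.cos(theta)
    sigma = params.fiber_width / 2.355
    blurred = gaussian_filter(canvas, sigma)
    if blurred.max() > 0:
        blurred = blurred / blurred.max() * params.peak_intensity
    if params.heterogeneity > 0:
        field_ = gaussian_filter(rng.normal(size=shape), min(h, w) / 6.0)
        if field_.std() > 0:
            field_ = field_ / field_.std()
        blurred = blurred * (1.0 + params.heterogeneity * np.tanh(field_))
    return np.maximum(blurred, 0.0)


def _fb_map(
    shape: tuple[int, int], params: PhantomParams, rng: np.random.Generator
) -> np.ndarray:
    if params.constant_fb is not None:
        return np.full(shape, float(params.constant_fb))
    if params.fb_log_sigma == 0:
        return np.full(shape, float(params.fb_mean))
    field_ = gaussian_filter(rng.normal(size=shape), min(shape) / 8.0)
    if field_.std() > 0:
        field_ = field_ / field_.std()
    return params.fb_mean * np.exp(params.fb_log_sigma * field_ - params.fb_log_sigma**2 / 2)


def generate_image_pair(
    shape: tuple[int, int],
    params: PhantomParams | None = None,
    seed: int = 0,
    roi_id: str = "roi",
    region_type: str = "tumor_bulk",
    session_id: str = "session",
    empty: bool = False,
) -> tuple[ImagePair, ImageTruth]:
    """Generate one co-registered F/B phantom pair plus its ground truth.

    The B image is fiber intensity + background offset + noise; the F image is
    fiber intensity x the planted per-pixel ratio + background offset + noise.
    With ``empty=True`` no fibers are rendered (background-only frame). Noise
    is Gaussian with SD = noise_scale * sqrt(signal + 1), clipped at zero.
    """
    params = params or PhantomParams()
    h, w = int(shape[0]), int(shape[1])
    if h < 16 or w < 16:
        raise ValueError("shape must be at least 16x16")
    rng = np.random.default_rng(seed)
    fiber = (
        np.zeros((h, w)) if empty else _fiber_intensity((h, w), params, rng)
    )
    fb_map = _fb_map((h, w), params, rng)
    fiber_mask = fiber > 0.02 * params.peak_intensity
    if not empty and not fiber_mask.any():  # pragma: no cover - defensive
        raise RuntimeError("phantom rendered no fibers; increase n_fibers")

    b_clean = fiber + params.background_offset
    f_clean = fiber * fb_map + params.background_offset

    def _noised(clean: np.ndarray) -> np.ndarray:
        if params.noise_scale == 0:
            return clean
        sd = params.noise_scale * np.sqrt(clean + 1.0)
        return np.maximum(clean + rng.normal(0, 1, clean.shape) * sd, 0.0)

    pair = ImagePair(
        f_image=_noised(f_clean),
        b_image=_noised(b_clean),
        roi_id=roi_id,
        region_type=region_type,
        session_id=session_id,
    )
    truth = ImageTruth(
        true_fb_map=fb_map,
        fiber_mask_truth=fiber_mask,
        background_offset=params.background_offset,
        noise_scale=params.noise_scale,
    )
    return pair, truth


def write_image_pair(pair: ImagePair, directory: str | Path, scale: float = 1.0) -> tuple[Path, Path]:
    """Write F and B as 16-bit grayscale TIFFs named ``<roi_id>_F.tif`` / ``_B.tif``."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix, img in (("F", pair.f_image), ("B", pair.b_image)):
        arr = np.clip(np.round(img * scale), 0, 65535).astype(np.uint16)
        p = directory / f"{pair.roi_id}_{suffix}.tif"
        tifffile.imwrite(p, arr)
        paths.append(p)
    return paths[0], paths[1]


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortTruth:
    """Planted survival structure for a synthetic patient cohort.

    Log hazard is linear in interface ln F/B (protective by default, i.e.
    ``beta_interface < 0``), bulk ln F/B, and the S-ODX score; event times are
    exponential given the linear predictor, with independent exponential
    censoring. Defaults put ln F/B on the scale seen for adaptive-threshold
    measurements (interface around 2.9, bulk around 2.4) and the event/censor
    rates on a months scale with a realistic event fraction.
    """

    beta_interface: float = -0.8
    beta_bulk: float = 0.0
    beta_sodx: float = 0.03
    baseline_rate: float = 0.04  # events per month at covariates 0
    censor_rate: float = 0.005
    rho_bulk_interface: float = 0.4
    mean_ln_interface: float = 2.9
    sd_ln_interface: float = 0.4
    mean_ln_bulk: float = 2.4
    sd_ln_bulk: float = 0.5
    sodx_mean: float = 22.0
    sodx_sd: float = 10.0

    def __post_init__(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if abs(self.rho_bulk_interface) > 1:
            raise ValueError("|rho_bulk_interface| must be <= 1")


def generate_cohort(
    n_patients: int, truth: CohortTruth | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a synthetic cohort table with planted proportional-hazards risk.

    Columns: patient_id, ln_fb_bulk, ln_fb_interface, fb_bulk, fb_interface,
    sodx, mfs_time, event, plus the per-patient true event and censor times.
    """
    truth = truth or CohortTruth()
    if n_patients < 4:
        raise ValueError("need at least 4 patients (quartiles undefined below that)")
    rng = np.random.default_rng(seed)
    cov = truth.rho_bulk_interface * truth.sd_ln_bulk * truth.sd_ln_interface
    mean = [truth.mean_ln_bulk, truth.mean_ln_interface]
    cov_matrix = [
        [truth.sd_ln_bulk**2, cov],
        [cov, truth.sd_ln_interface**2],
    ]
    ln_fb = rng.multivariate_normal(mean, cov_matrix, size=n_patients)
    sodx = np.clip(rng.normal(truth.sodx_mean, truth.sodx_sd, n_patients), 0.0, 100.0)
    eta = (
        truth.beta_interface * ln_fb[:, 1]
        + truth.beta_bulk * ln_fb[:, 0]
        + truth.beta_sodx * sodx
    )
    rate = truth.baseline_rate * np.exp(eta)
    event_time = rng.exponential(1.0 / rate)
    if truth.censor_rate > 0:
        censor_time = rng.exponential(1.0 / truth.censor_rate, n_patients)
    else:
        censor_time = np.full(n_patients, np.inf)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "ln_fb_bulk": ln_fb[:, 0],
            "ln_fb_interface": ln_fb[:, 1],
            "fb_bulk": np.exp(ln_fb[:, 0]),
            "fb_interface": np.exp(ln_fb[:, 1]),
            "sodx": sodx,
            "mfs_time": observed,
            "event": event,
            "true_event_time": event_time,
            "true_censor_time": censor_time,
        }
    )


@dataclass(frozen=True)
class TreeCohortTruth:
    """Piecewise (three-risk-group) hazard plant for risk-tree recovery.

    Risk is a step function of interface ln F/B at ``fb_cut`` and, within the
    higher-F/B (lower-risk) branch, of S-ODX at ``sodx_cut`` — the structure a
    relative-risk tree should recover: highest risk below the F/B cut, then
    moderate/low risk above it depending on S-ODX.
    """

    fb_cut: float = 2.65
    sodx_cut: float = 25.5
    hazard_high: float = 0.020  # ln F/B below fb_cut
    hazard_mid: float = 0.008  # ln F/B >= fb_cut, S-ODX >= sodx_cut
    hazard_low: float = 0.002  # ln F/B >= fb_cut, S-ODX < sodx_cut
    censor_rate: float = 0.003
    rho_bulk_interface: float = 0.5


def generate_tree_cohort(
    n_patients: int, truth: TreeCohortTruth | None = None, seed: int = 0
) -> pd.DataFrame:
    """Cohort whose hazard is the planted three-group step model."""
    truth = truth or TreeCohortTruth()
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    rng = np.random.default_rng(seed)
    cov = truth.rho_bulk_interface * 0.5 * 0.4
    ln_fb = rng.multivariate_normal(
        [2.4, 2.9], [[0.5**2, cov], [cov, 0.4**2]], size=n_patients
    )
    sodx = np.clip(rng.normal(22.0, 10.0, n_patients), 0.0, 100.0)
    low_fb = ln_fb[:, 1] < truth.fb_cut
    rate = np.where(
        low_fb,
        truth.hazard_high,
        np.where(sodx >= truth.sodx_cut, truth.hazard_mid, truth.hazard_low),
    )
    event_time = rng.exponential(1.0 / rate)
    censor_time = (
        rng.exponential(1.0 / truth.censor_rate, n_patients)
        if truth.censor_rate > 0
        else np.full(n_patients, np.inf)
    )
    observed = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n_patients)],
            "ln_fb_bulk": ln_fb[:, 0],
            "ln_fb_interface": ln_fb[:, 1],
            "sodx": sodx,
            "mfs_time": observed,
            "event": (event_time <= censor_time).astype(int),
        }
    )


def generate_calibration_record(
    session_id: str, true_fitc_fb: float, seed: int = 0, noise_sd: float = 0.0
) -> CalibrationRecord:
    """Session-level FITC reference F/B, optionally with log-normal measurement noise."""
    if not true_fitc_fb > 0:
        raise ValueError("true_fitc_fb must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    value = float(true_fitc_fb)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        value *= float(np.exp(rng.normal(0.0, noise_sd)))
    return CalibrationRecord(session_id=session_id, fitc_fb=value)


def write_settings_sidecar(params: object, path: str | Path) -> Path:
    """Echo a generation-settings dataclass to a JSON sidecar."""
    path = Path(path)
    payload = asdict(params) if hasattr(params, "__dataclass_fields__") else dict(params)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_default))
    return path
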