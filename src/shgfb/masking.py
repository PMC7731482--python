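"""Binary collagen-pixel masks from SHG intensity images.

Three mask-generation routes are provided, mirroring how fiber pixels are
separated from background in F/B scattering analysis:

* ``manual_mask`` — a fixed intensity threshold chosen per image (standing in
  for a blinded observer picking the level that best separates fibers from
  background).
* ``otsu_mask`` — histogram thresholding: the threshold minimizing the
  weighted sum of within-class variances, scaled by a factor (default 0.6)
  before binarization.
* ``adaptive_mask`` — per-pixel binarization against a factor (default 0.6)
  of the mean intensity in a square window centered on the pixel, with the
  window size chosen automatically so that no window position can sit wholly
  inside collagen-free background.

All binarizations use a strict ``>`` comparison: ties at the threshold go to
background. Masks from the F and B channels are combined with an elementwise
product (``combine_masks``) so only pixels bright in both channels survive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "ThresholdSettings",
    "manual_mask",
    "otsu_threshold",
    "otsu_mask",
    "select_window_size",
    "adaptive_mask",
    "combine_masks",
    "default_window_sequence",
]


@dataclass(frozen=True)
class BinaryMask:
    """A 0/1 mask plus provenance (which method, which channel)."""

    values: np.ndarray
    method: str  # {"manual", "otsu", "adaptive"}
    source: str  # {"F", "B", "combined"}

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def default_window_sequence(shape: tuple[int, int]) -> tuple[int, ...]:
    """Descending odd window sizes: largest odd <= min(H,W)/2, halving, down to 9."""
    top = min(shape) // 2
    cur = top if top % 2 == 1 else top - 1
    seq: list[int] = []
    while cur >= 9:
        seq.append(cur)
        nxt = cur // 2
        cur = nxt if nxt % 2 == 1 else nxt - 1
    if not seq:
        raise ValueError(f"image too small for adaptive windowing: shape={shape}")
    if seq[-1] != 9:
        seq.append(9)
    return tuple(seq)


@dataclass(frozen=True)
class ThresholdSettings:
    """Tunables shared by the three masking methods.

    otsu_scale      multiplies the Otsu threshold value before binarization.
    adaptive_factor multiplies the (global or local) mean in adaptive masking.
    empty_fraction  a window position with a nonzero-pixel fraction below this
                    counts as "fits in collagen-free background".
    window_sequence descending odd window sizes tried by select_window_size;
                    None derives a sequence from the image shape at call time.
    """

    otsu_scale: float = 0.6
    adaptive_factor: float = 0.6
    empty_fraction: float = 0.05
    window_sequence: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.otsu_scale > 0:
            raise ValueError("otsu_scale must be positive")
        if not self.adaptive_factor > 0:
            raise ValueError("adaptive_factor must be positive")
        if not 0 < self.empty_fraction < 1:
            raise ValueError("empty_fraction must lie in (0, 1)")
        if self.window_sequence is not None:
            ws = tuple(int(w) for w in self.window_sequence)
            if not ws:
                raise ValueError("window_sequence must be non-empty")
            if any(w <= 0 or w % 2 == 0 for w in ws):
                raise ValueError("window sizes must be odd positive integers")
            if any(a <= b for a, b in zip(ws, ws[1:])):
                raise ValueError("window_sequence must be strictly decreasing")
            object.__setattr__(self, "window_sequence", ws)

    def windows_for(self, shape: tuple[int, int]) -> tuple[int, ...]:
        if self.window_sequence is not None:
            if self.window_sequence[0] > min(shape):
                raise ValueError(
                    f"largest window {self.window_sequence[0]} exceeds image size {min(shape)}"
                )
            return self.window_sequence
        return default_window_sequence(shape)


def _as_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D intensity array")
    return img


def manual_mask(image: np.ndarray, threshold: float, source: str = "F") -> BinaryMask:
    """Binarize at a user-supplied intensity threshold (pixel > threshold -> 1)."""
    img = _as_image(image)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return BinaryMask((img > threshold).astype(np.uint8), "manual", source)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive histogram threshold minimizing weighted within-class variance.

    Candidate thresholds are the exact distinct pixel values for integer
    images, or ``n_bins`` evenly spaced levels over [min, max] for float
    images. The returned threshold ``t`` partitions pixels into background
    (``<= t``) and foreground (``> t``); the objective is
    ``w_bg * var_bg + w_fg * var_fg`` with weights the class pixel fractions.
    Ties are broken toward the smallest threshold.
    """
    img = _as_image(image).ravel()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = np.unique(img)
    if vals.size < 2:
        raise ValueError("constant image: Otsu threshold undefined")
    if np.issubdtype(img.dtype, np.integer):
        # all distinct levels except the max (which would empty the foreground)
        candidates = vals[:-1].astype(np.float64)
    else:
        lo, hi = float(vals[0]), float(vals[-1])
        candidates = np.linspace(lo, hi, n_bins, dtype=np.float64)[:-1]

    x = img.astype(np.float64)
    order = np.sort(x)
    n = x.size
    csum = np.cumsum(order)
    csum2 = np.cumsum(order**2)
    # number of pixels <= t for each candidate
    k = np.searchsorted(order, candidates, side="right")
    valid = (k > 0) & (k < n)
    k = k[valid]
    cands = candidates[valid]
    s_bg, s2_bg = csum[k - 1], csum2[k - 1]
    s_fg, s2_fg = csum[-1] - s_bg, csum2[-1] - s2_bg
    n_bg = k.astype(np.float64)
    n_fg = n - n_bg
    var_bg = s2_bg / n_bg - (s_bg / n_bg) ** 2
    var_fg = s2_fg / n_fg - (s_fg / n_fg) ** 2
    objective = (n_bg / n) * var_bg + (n_fg / n) * var_fg
    return float(cands[np.argmin(objective)])


def otsu_mask(
    image: np.ndarray, settings: ThresholdSettings | None = None, source: str = "F"
) -> BinaryMask:
    """Binarize at ``otsu_scale``x the Otsu threshold (pixel > scaled value -> 1)."""
    settings = settings or ThresholdSettings()
    img = _as_image(image)
    t = settings.otsu_scale * otsu_threshold(img)
    return BinaryMask((img > t).astype(np.uint8), "otsu", source)


def _window_sums(arr: np.ndarray, k: int) -> np.ndarray:
    """Sums over all k-by-k windows fully inside ``arr`` (valid positions only)."""
    s = np.cumsum(np.cumsum(np.pad(arr, ((1, 0), (1, 0))), axis=0), axis=1)
    return s[k:, k:] - s[:-k, k:] - s[k:, :-k] + s[:-k, :-k]


def _clipped_local_mean(img: np.ndarray, k: int) -> np.ndarray:
    """Mean over the k-by-k window centered at each pixel, clipped to the image."""
    h = k // 2
    padded = np.pad(img.astype(np.float64), h)
    sums = _window_sums(padded, k)
    ones = np.pad(np.ones(img.shape), h)
    counts = _window_sums(ones, k)
    return sums / counts


def select_window_size(
    image: np.ndarray, settings: ThresholdSettings | None = None
) -> int:
    """Smallest window that cannot sit wholly inside collagen-free background.

    The image is first binarized at ``adaptive_factor`` times its global mean
    intensity. For each candidate size (largest first) the fraction of nonzero
    pixels is computed at every fully-interior window position; a size is
    admissible when even its emptiest position holds at least
    ``empty_fraction`` nonzero pixels. The smallest admissible size is
    returned. If no size is admissible — every candidate window fits into an
    empty region somewhere — the largest size is returned with a warning.
    """
    settings = settings or ThresholdSettings()
    img = _as_image(image)
    seq = settings.windows_for(img.shape)
    binary = (img > settings.adaptive_factor * img.mean()).astype(np.int64)
    if binary.sum() == 0:
        raise ValueError("no foreground after pre-binarization; cannot size window")
    chosen: int | None = None
    for k in seq:  # descending
        min_frac = _window_sums(binary, k).min() / (k * k)
        if min_frac >= settings.empty_fraction:
            chosen = k  # admissible; keep looking for a smaller one
        else:
            # a failing size fits into an empty region; smaller sizes fit even
            # more easily, so the search stops one step above the first failure
            break
    if chosen is None:
        warnings.warn(
            f"even the largest window ({seq[0]} px) fits entirely into "
            "collagen-free background; using it anyway",
            stacklevel=2,
        )
        logger.warning("select_window_size: no admissible size in %s", seq)
        return seq[0]
    return chosen


def adaptive_mask(
    image: np.ndarray,
    settings: ThresholdSettings | None = None,
    source: str = "F",
    window_size: int | None = None,
) -> BinaryMask:
    """Per-pixel binarization against ``adaptive_factor``x the local window mean.

    The window size defaults to ``select_window_size(image, settings)``.
    Foreground is bright: mask = 1 where pixel > factor * local mean, with
    edge windows clipped to the image bounds.
    """
    settings = settings or ThresholdSettings()
    img = _as_image(image)
    k = window_size if window_size is not None else select_window_size(img, settings)
    local_mean = _clipped_local_mean(img, k)
    return BinaryMask(
        (img > settings.adaptive_factor * local_mean).astype(np.uint8),
        "adaptive",
        source,
    )


def combine_masks(mask_f: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Elementwise product: 1 only where both channel masks are 1."""
    if mask_f.values.shape != mask_b.values.shape:
        raise ValueError(
            f"mask shapes differ: {mask_f.values.shape} vs {mask_b.values.shape}"
        )
    if mask_f.method != mask_b.method:
        raise ValueError(f"mask methods differ: {mask_f.method} vs {mask_b.method}")
    return BinaryMask(mask_f.values * mask_b.values, mask_f.method, "combined")
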