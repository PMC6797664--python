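"""Preprocessing of CE+NBI endoscopic frames.

A raw colour frame is reduced to the triple of processed images the
indicator stage consumes:

* ``I_H`` — the grey frame with its low-frequency illumination trend
  removed by a Daubechies-7 wavelet decomposition applied to every row
  and then every column (the "homogenized" image);
* ``I_F`` — the multi-scale Frangi vesselness response of ``I_H``,
  rescaled to [0, 1];
* ``I_S`` — the binary vessel skeleton, obtained by Otsu thresholding of
  ``I_F`` followed by iterative thinning to one-pixel-wide centrelines.

All stages are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt
from skimage.filters import frangi, threshold_otsu
from skimage.morphology import thin

__all__ = [
    "PreprocessConfig",
    "ProcessedImages",
    "to_gray",
    "detrend",
    "frangi_enhance",
    "binarize_skeletonize",
    "preprocess_frame",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the preprocessing stage.

    Parameters
    ----------
    channel:
        Colour-to-grey policy. ``"green"`` extracts the green plane (NBI
        maximizes vessel contrast in the green band); ``"luminance"``
        uses the Rec.601 weighted average.
    wavelet, wavelet_level:
        Wavelet family and decomposition depth used for detrending.
    sigmas:
        Frangi scales in pixels; 1..8 covers capillary to dilated-IPCL
        widths at contact-endoscope magnification.
    black_ridges:
        If True, detect dark vessels on a bright background (the NBI
        appearance; vessels absorb the narrow-band light).
    otsu_floor:
        Vesselness responses at or below this value are treated as flat
        background and excluded from the Otsu histogram.
    """

    channel: str = "green"
    wavelet: str = "db7"
    wavelet_level: int = 7
    sigmas: tuple[float, ...] = tuple(float(s) for s in range(1, 9))
    black_ridges: bool = True
    otsu_floor: float = 1e-3


@dataclass(frozen=True)
class ProcessedImages:
    """The triple (I_H, I_F, I_S) derived from one frame."""

    enhanced: np.ndarray  # I_H, float
    filtered: np.ndarray  # I_F, float in [0, 1]
    skeleton: np.ndarray  # I_S, bool

    def __post_init__(self) -> None:
        if not (self.enhanced.shape == self.filtered.shape == self.skeleton.shape):
            raise ValueError("I_H, I_F and I_S must share the frame's dimensions")


def to_gray(frame: np.ndarray, channel: str = "green") -> np.ndarray:
    """Convert a colour frame to a single float grey plane.

    Integer inputs are rescaled to [0, 1] by their dtype maximum; float
    inputs are passed through unscaled.  2-D input is returned as-is
    (cast to float).
    """
    frame = np.asarray(frame)
    if np.issubdtype(frame.dtype, np.integer):
        frame = frame.astype(np.float64) / np.iinfo(frame.dtype).max
    else:
        frame = frame.astype(np.float64)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 3:
        if channel == "green":
            return frame[:, :, 1].copy()
        if channel == "luminance":
            return frame @ np.array([0.299, 0.587, 0.114])
        raise ValueError(f"unknown channel policy: {channel!r}")
    raise ValueError(f"expected a 2-D or HxWx3 image, got shape {frame.shape}")


def detrend(img: np.ndarray, wavelet: str = "db7", level: int = 7) -> np.ndarray:
    """Remove the low-frequency illumination trend from a grey image.

    Every row is decomposed to ``level`` scales with the given wavelet,
    the approximation coefficients are zeroed and the row reconstructed;
    the same is then applied to every column of the row-detrended image.
    Equivalent to subtracting the level-``level`` approximation in each
    direction.  Symmetric boundary extension.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detrend expects a 2-D image")
    if min(img.shape) < 2**level:
        raise ValueError(
            f"image {img.shape} too small for a level-{level} decomposition"
        )
    out = _detrend_axis(img, wavelet, level, axis=1)   # rows
    out = _detrend_axis(out, wavelet, level, axis=0)   # columns
    return out


def _detrend_axis(a: np.ndarray, wavelet: str, level: int, axis: int) -> np.ndarray:
    with warnings.catch_warnings():
        # pywt warns when `level` exceeds the boundary-free maximum; the
        # symmetric extension keeps the reconstruction well defined.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(a, wavelet, mode="symmetric", level=level, axis=axis)
    coeffs[0] = np.zeros_like(coeffs[0])
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric", axis=axis)
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(0, a.shape[axis])
    return rec[tuple(sl)]


def frangi_enhance(
    img: np.ndarray,
    sigmas: Sequence[float] = tuple(range(1, 9)),
    black_ridges: bool = True,
) -> np.ndarray:
    """Multi-scale Frangi vesselness of a grey image, rescaled to [0, 1].

    The response at each pixel is the maximum over the given Hessian
    scales; the correction constants keep their standard defaults.
    """
    sigmas = tuple(float(s) for s in sigmas)
    if not sigmas or any(s <= 0 for s in sigmas):
        raise ValueError("sigmas must be non-empty and positive")
    img = np.asarray(img, dtype=np.float64)
    # a numerically constant image has no ridge structure; the filter's
    # scale-adaptive normalization would otherwise amplify float noise
    if np.ptp(img) <= 1e-12 * max(1.0, np.abs(img).max()):
        return np.zeros_like(img)
    resp = frangi(img, sigmas=sigmas, black_ridges=black_ridges)
    top = resp.max()
    if top > 0:
        resp = resp / top
    return np.clip(resp, 0.0, 1.0)


def binarize_skeletonize(filtered: np.ndarray, otsu_floor: float = 1e-3) -> np.ndarray:
    """Threshold a vesselness map and thin it to a 1-px-wide skeleton.

    The Otsu threshold is computed over responses above ``otsu_floor``
    only, so the (typically vast) flat background does not dominate the
    histogram.  An all-background map yields an empty skeleton.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    fg = filtered[filtered > otsu_floor]
    if fg.size == 0:
        return np.zeros(filtered.shape, dtype=bool)
    if np.ptp(fg) == 0:
        # constant foreground (already-binary response): nothing to split
        return thin(filtered > otsu_floor)
    t = threshold_otsu(fg)
    return thin(filtered >= t)


def preprocess_frame(
    frame: np.ndarray, config: PreprocessConfig | None = None
) -> ProcessedImages:
    """Run the full preprocessing chain on one frame."""
    cfg = config or PreprocessConfig()
    gray = to_gray(frame, channel=cfg.channel)
    enhanced = detrend(gray, wavelet=cfg.wavelet, level=cfg.wavelet_level)
    filtered = frangi_enhance(enhanced, sigmas=cfg.sigmas, black_ridges=cfg.black_ridges)
    skeleton = binarize_skeletonize(filtered, otsu_floor=cfg.otsu_floor)
    return ProcessedImages(enhanced=enhanced, filtered=filtered, skeleton=skeleton)
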