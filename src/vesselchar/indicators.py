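"""The five per-image disorder indicators.

Two indicators describe the consistency of vessel *direction*:

* **HGD** — magnitude-weighted, unit-sum histogram of the gradient
  directions of the enhanced image I_H.  Parallel vessels concentrate
  the gradient energy in two opposite angles; chaotic patterns flatten
  the histogram.
* **RIA** — rotational image averaging of the vesselness map I_F: the
  image is rotated through 0°..315° in 45° steps and the row means of
  each rotation are concatenated.  Parallel vessels aligned with a
  rotation produce a few tall peaks; curved vessels smear the profile.

Three indicators describe *curvature*, computed on vessel segments
longer than 20 px traced from the skeleton I_S:

* **DIS** — per skeleton pixel C, the Euclidean distance d(A, C) to the
  segment's reference point A.
* **ANG** — per skeleton pixel C, the angle between the baseline vector
  AB and AC, in [0°, 180°].
* **CUR** — per-pixel curvature along each path (tangent-orientation
  change per unit arc length), concatenated over segments.

A simple prominence-based peak detector, shared by the feature stage,
also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .segments import SegmentSet

__all__ = [
    "IndicatorConfig",
    "IndicatorSet",
    "PeakSet",
    "compute_hgd",
    "compute_ria",
    "compute_ang_dis",
    "compute_cur",
    "compute_indicators",
    "detect_peaks",
]

RIA_ANGLES: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)


@dataclass(frozen=True)
class IndicatorConfig:
    """Parameters of the indicator stage.

    ``hgd_bins`` resolves 2° direction structure; ``hgd_percentile`` is
    the magnitude quantile above which a gradient counts as
    "significant".  ``cur_window`` is the half-width (px) of the tangent
    estimation window along a path.
    """

    hgd_bins: int = 180
    hgd_percentile: float = 0.75
    hgd_weighted: bool = True
    ria_angles: tuple[float, ...] = RIA_ANGLES
    cur_window: int = 5
    min_segment_len: int = 21


@dataclass(frozen=True)
class IndicatorSet:
    """The five indicator signals of one image.

    ``ang`` and ``dis`` are per-segment collections (one 1-D array per
    vessel segment, the paper's cell format); the others are flat 1-D
    signals.
    """

    hgd: np.ndarray
    ria: np.ndarray
    ang: tuple[np.ndarray, ...]
    dis: tuple[np.ndarray, ...]
    cur: np.ndarray


@dataclass(frozen=True)
class PeakSet:
    """Significant peaks of a 1-D signal.

    ``onset``/``offset`` are the nearest flanking local minima of each
    peak (clipped at the signal ends) and delimit the peak waveform used
    for energy sums; ``amplitude`` is the peak prominence; ``width`` is
    the full width at half prominence, in samples.
    """

    index: np.ndarray
    onset: np.ndarray
    offset: np.ndarray
    amplitude: np.ndarray
    width: np.ndarray

    @property
    def n_p(self) -> int:
        return len(self.index)


def compute_hgd(
    enhanced: np.ndarray,
    n_bins: int = 180,
    mag_percentile: float = 0.75,
    weighted: bool = True,
) -> np.ndarray:
    """Histogram of significant gradient directions of I_H.

    Gradients use central differences; pixels whose gradient magnitude
    exceeds the ``mag_percentile`` quantile of the nonzero magnitudes
    are binned by direction over [0°, 360°), each weighted by its
    magnitude (or counted once if ``weighted`` is False), and the
    histogram is normalized to unit sum.  A constant image yields an
    all-zero histogram.
    """
    img = np.asarray(enhanced, dtype=np.float64)
    gr, gc = np.gradient(img)
    mag = np.hypot(gr, gc)
    nz = mag[mag > 0]
    hist = np.zeros(n_bins, dtype=np.float64)
    if nz.size == 0:
        return hist
    thr = np.quantile(nz, mag_percentile)
    sel = mag > thr
    if not sel.any():
        return hist
    ang = np.degrees(np.arctan2(gr[sel], gc[sel])) % 360.0
    w = mag[sel] if weighted else np.ones(sel.sum())
    hist, _ = np.histogram(ang, bins=n_bins, range=(0.0, 360.0), weights=w)
    total = hist.sum()
    return hist / total if total > 0 else hist


def ria_rotations(
    filtered: np.ndarray, angles: tuple[float, ...] = RIA_ANGLES
) -> list[tuple[float, np.ndarray]]:
    """Per-rotation row-mean profiles s_row^θ of I_F.

    Each rotation expands the canvas (zero fill) so no vessel pixel is
    cropped; the profile is the mean of each row across its columns.
    """
    img = np.asarray(filtered, dtype=np.float64)
    out = []
    for theta in angles:
        if theta % 360.0 == 0.0:
            rot = img
        else:
            rot = ndimage.rotate(img, theta, reshape=True, order=1, cval=0.0)
        out.append((theta, rot.mean(axis=1)))
    return out


def compute_ria(
    filtered: np.ndarray, angles: tuple[float, ...] = RIA_ANGLES
) -> np.ndarray:
    """Concatenated rotational row averages of I_F, in angle order."""
    return np.concatenate([s for _, s in ria_rotations(filtered, angles)])


def compute_ang_dis(
    segset: SegmentSet,
) -> tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...]]:
    """Per-segment angle and distance signals about the reference points.

    For each path pixel C of segment m: DIS = ‖AC‖ (Euclidean) and
    ANG = atan2(‖AB×AC‖, AB·AC) in degrees, which maps collinear points
    to 0°/180° and keeps obtuse angles unfolded.  C = A gives distance 0
    and angle 0 by convention.
    """
    angs, diss = [], []
    for seg in segset:
        a = np.asarray(seg.ref_a, dtype=np.float64)
        b = np.asarray(seg.ref_b, dtype=np.float64)
        ab = b - a
        ac = seg.path.astype(np.float64) - a
        dist = np.hypot(ac[:, 0], ac[:, 1])
        cross = np.abs(ab[0] * ac[:, 1] - ab[1] * ac[:, 0])
        dot = ac @ ab
        theta = np.degrees(np.arctan2(cross, dot))
        theta[dist == 0] = 0.0
        angs.append(theta)
        diss.append(dist)
    return tuple(angs), tuple(diss)


def segment_curvature(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Signed curvature (px⁻¹) at every pixel of one ordered path.

    The tangent direction at each pixel is estimated by total
    least-squares over the ±``window`` neighbouring pixels (truncated at
    the path ends), oriented along the walk; curvature is the derivative
    of the unwrapped tangent angle with respect to arc length.  The
    windowed fit suppresses the staircase quantization of digital
    curves, so straight digital lines measure (near) zero curvature.
    """
    pts = np.asarray(path, dtype=np.float64)
    n = len(pts)
    if n < 2:
        return np.zeros(n)
    idx = np.arange(n)
    lo = np.maximum(0, idx - window)
    hi = np.minimum(n, idx + window + 1)
    u, v = pts[:, 0], pts[:, 1]

    def wsum(a: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(a)])
        return cs[hi] - cs[lo]

    m = (hi - lo).astype(np.float64)
    su, sv = wsum(u), wsum(v)
    cuu = wsum(u * u) - su * su / m
    cvv = wsum(v * v) - sv * sv / m
    cuv = wsum(u * v) - su * sv / m
    # principal-axis angle of the 2x2 window covariance (mod pi) ...
    alpha = 0.5 * np.arctan2(2.0 * cuv, cuu - cvv)
    d = np.stack([np.cos(alpha), np.sin(alpha)], axis=1)
    # ... oriented along the walk by the window chord
    chord = pts[hi - 1] - pts[lo]
    d[(d * chord).sum(axis=1) < 0] *= -1
    theta = np.unwrap(np.arctan2(d[:, 0], d[:, 1]))
    # Average the tangent angle over ~3 windows: the residual staircase
    # wobble of shallow digital lines is periodic with zero mean, so a
    # moving average cancels it without biasing genuine curvature much.
    width = 3 * window + (1 - (3 * window) % 2)
    theta = ndimage.uniform_filter1d(theta, size=width, mode="nearest")
    step = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(step)])
    if s[-1] == 0:
        return np.zeros(n)
    return np.gradient(theta, s)


def compute_cur(segset: SegmentSet, window: int = 5) -> np.ndarray:
    """Concatenated per-pixel curvature over all vessel segments."""
    parts = [segment_curvature(seg.path, window=window) for seg in segset]
    if not parts:
        return np.zeros(0)
    return np.concatenate(parts)


def detect_peaks(
    sig: np.ndarray, prominence_frac: float = 0.1, min_prominence: float = 0.0
) -> PeakSet:
    """Find significant peaks of a 1-D signal.

    A local maximum is significant when its prominence reaches
    ``prominence_frac`` of the signal's total range (and, when a signal
    has a meaningful absolute scale such as curvature in px⁻¹, at least
    ``min_prominence`` in the signal's own units).  Onset/offset are
    the nearest local minima on each side (signal ends included), the
    amplitude is the prominence and the width the full width at half
    prominence.
    """
    x = np.asarray(sig, dtype=np.float64)
    empty = PeakSet(*(np.zeros(0, dtype=int),) * 3, np.zeros(0), np.zeros(0))
    if x.size < 3 or np.ptp(x) == 0:
        return empty
    prom = max(prominence_frac * np.ptp(x), min_prominence)
    idx, props = signal.find_peaks(x, prominence=prom)
    if idx.size == 0:
        return empty
    widths = signal.peak_widths(x, idx, rel_height=0.5)[0]
    onset = np.array([_nearest_min(x, i, -1) for i in idx])
    offset = np.array([_nearest_min(x, i, +1) for i in idx])
    return PeakSet(
        index=idx,
        onset=onset,
        offset=offset,
        amplitude=props["prominences"],
        width=widths,
    )


def _nearest_min(x: np.ndarray, i: int, step: int) -> int:
    """Index of the nearest local minimum from peak ``i`` walking by ``step``.

    A candidate must lie strictly below the peak so the flat top of a
    plateau peak is never taken for its own base.
    """
    n = len(x)
    j = i + step
    while 0 < j < n - 1:
        if x[j] < x[i] and x[j] <= x[j - 1] and x[j] <= x[j + 1]:
            return j
        j += step
    return int(np.clip(j, 0, n - 1))


def compute_indicators(
    enhanced: np.ndarray,
    filtered: np.ndarray,
    segset: SegmentSet,
    config: IndicatorConfig | None = None,
) -> IndicatorSet:
    """Compute the full five-indicator set of one image."""
    cfg = config or IndicatorConfig()
    hgd = compute_hgd(
        enhanced,
        n_bins=cfg.hgd_bins,
        mag_percentile=cfg.hgd_percentile,
        weighted=cfg.hgd_weighted,
    )
    ria = compute_ria(filtered, angles=cfg.ria_angles)
    ang, dis = compute_ang_dis(segset)
    cur = compute_cur(segset, window=cfg.cur_window)
    return IndicatorSet(hgd=hgd, ria=ria, ang=ang, dis=dis, cur=cur)
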