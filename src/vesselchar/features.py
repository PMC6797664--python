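"""The 24 scalar features F1–F24 derived from the five indicators.

Block layout (fixed, versioned in the CSV header):

* F1–F4   — HGD: total energy, minimum, range, peak-energy ratio.
* F5–F8   — RIA: total energy, peak count, mean-peak-energy ratio,
  mean amplitude/width ratio.
* F9–F14  — ANG: mean/total/max/median of the per-segment derivative
  sign-change counts, then mean/median cubic-fit RMS error.
* F15–F20 — DIS: same six statistics as the ANG block.
* F21–F24 — CUR: total energy, variance, peak count, peak count times
  summed peak amplitude.

Degenerate inputs (blank image, no peaks, no segments) produce feature
value 0, never NaN, so downstream classifiers always see finite inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .indicators import IndicatorSet, PeakSet, detect_peaks

__all__ = [
    "FEATURE_NAMES",
    "hgd_features",
    "ria_features",
    "sign_change_counts",
    "aggregate_sign_changes",
    "sign_change_features",
    "polyfit_error_features",
    "cur_features",
    "extract_all",
]

FEATURE_NAMES: tuple[str, ...] = tuple(f"F{i}" for i in range(1, 25))


def _peak_energy(sig: np.ndarray, peaks: PeakSet) -> float:
    """Energy of the union of peak waveforms (onset..offset inclusive).

    Adjacent peaks may share a flanking minimum; taking the union keeps
    each sample counted once so the peak-energy ratio stays ≤ 1.
    """
    mask = np.zeros(len(sig), dtype=bool)
    for on, off in zip(peaks.onset, peaks.offset):
        mask[on : off + 1] = True
    return float(np.sum(np.asarray(sig)[mask] ** 2))


def _per_peak_energies(sig: np.ndarray, peaks: PeakSet) -> np.ndarray:
    sig = np.asarray(sig)
    return np.array(
        [np.sum(sig[on : off + 1] ** 2) for on, off in zip(peaks.onset, peaks.offset)]
    )


def hgd_features(hgd: np.ndarray, peaks: PeakSet) -> tuple[float, float, float, float]:
    """F1 energy, F2 minimum, F3 range, F4 peak-energy / total-energy."""
    hgd = np.asarray(hgd, dtype=np.float64)
    if hgd.size == 0 or not hgd.any():
        return 0.0, 0.0, 0.0, 0.0
    f1 = float(np.sum(hgd**2))
    f2 = float(hgd.min())
    f3 = float(hgd.max() - hgd.min())
    f4 = _peak_energy(hgd, peaks) / f1 if (f1 > 0 and peaks.n_p > 0) else 0.0
    return f1, f2, f3, f4


def ria_features(ria: np.ndarray, peaks: PeakSet) -> tuple[float, float, float, float]:
    """F5 energy, F6 peak count, F7 mean-peak-energy ratio, F8 amp/width."""
    ria = np.asarray(ria, dtype=np.float64)
    if ria.size == 0 or not ria.any():
        return 0.0, 0.0, 0.0, 0.0
    f5 = float(np.sum(ria**2))
    f6 = float(peaks.n_p)
    if peaks.n_p == 0 or f5 == 0:
        return f5, f6, 0.0, 0.0
    f7 = float(np.mean(_per_peak_energies(ria, peaks))) / f5
    f8 = float(np.mean(peaks.amplitude / peaks.width))
    return f5, f6, f7, f8


#: Derivative magnitudes below these are treated as zero when counting
#: sign changes.  ANG values are degrees: a skeleton pixel quantized by
#: ±0.5 px some tens of pixels from the reference point jitters the
#: angle by a fraction of a degree per sample, which is measurement
#: noise, not vessel geometry.  DIS advances ~1 px per path pixel, so
#: its quantization floor is far below real direction reversals.
ANG_DERIV_DEADBAND = 0.5   # degrees / sample
DIS_DERIV_DEADBAND = 0.05  # px / sample


def sign_change_counts(
    sequences, deriv_window: int = 5, deadband: float = 0.0
) -> np.ndarray:
    """Number of derivative sign changes s_m of each per-segment signal.

    The derivative is a 5-point quadratic Savitzky–Golay filter
    (shrunk to the sequence length when needed); derivative values
    within ``deadband`` of zero are skipped, so a +,0,− pattern counts
    one change.
    """
    out = []
    for seq in sequences:
        seq = np.asarray(seq, dtype=np.float64)
        if seq.size < 3:
            out.append(0)
            continue
        win = min(deriv_window, seq.size if seq.size % 2 else seq.size - 1)
        d = savgol_filter(seq, win, polyorder=min(2, win - 1), deriv=1)
        signs = np.sign(d) * (np.abs(d) > deadband)
        signs = signs[signs != 0]
        out.append(int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0)
    return np.asarray(out, dtype=np.float64)


def aggregate_sign_changes(s) -> tuple[float, float, float, float]:
    """Mean, total, max and median of per-segment sign-change counts."""
    s = np.asarray(s, dtype=np.float64)
    if s.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    return float(s.mean()), float(s.sum()), float(s.max()), float(np.median(s))


def sign_change_features(
    sequences, deriv_window: int = 5, deadband: float = 0.0
) -> tuple[float, float, float, float]:
    """Sign-change aggregates computed from the per-segment signals."""
    return aggregate_sign_changes(
        sign_change_counts(sequences, deriv_window=deriv_window, deadband=deadband)
    )


def polyfit_error_features(sequences, degree: int = 3) -> tuple[float, float]:
    """Mean and median RMS residual of a cubic fit to each signal.

    Sequences shorter than ``degree + 1`` samples cannot constrain the
    fit and are excluded from the aggregates.
    """
    errs = []
    for seq in sequences:
        seq = np.asarray(seq, dtype=np.float64)
        if seq.size < degree + 1:
            continue
        g = np.arange(seq.size)
        coef = np.polynomial.polynomial.polyfit(g, seq, degree)
        resid = seq - np.polynomial.polynomial.polyval(g, coef)
        errs.append(float(np.sqrt(np.mean(resid**2))))
    if not errs:
        return 0.0, 0.0
    e = np.asarray(errs)
    return float(e.mean()), float(np.median(e))


def cur_features(cur: np.ndarray, peaks: PeakSet) -> tuple[float, float, float, float]:
    """F21 energy, F22 variance, F23 peak count, F24 n_p × Σ amplitudes.

    ``peaks`` are detected on |CUR|: the disorder signal is the size of
    the curvature excursions, not their turning sense.
    """
    cur = np.asarray(cur, dtype=np.float64)
    if cur.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    f21 = float(np.sum(cur**2))
    f22 = float(np.var(cur))
    f23 = float(peaks.n_p)
    f24 = float(peaks.n_p * peaks.amplitude.sum()) if peaks.n_p else 0.0
    return f21, f22, f23, f24


#: Curvature peaks must reach this absolute prominence (px⁻¹) besides
#: the relative criterion: a bend of radius ≳ 50 px is not a loop, and
#: an image whose largest curvature excursion sits below this floor has
#: no significant curvature structure to count.
CUR_MIN_PROMINENCE = 0.02


def extract_all(ind: IndicatorSet, prominence_frac: float = 0.1) -> np.ndarray:
    """Assemble the full 24-feature vector of one image.

    Peak detection uses the shared prominence-based detector on HGD,
    RIA and |CUR| (curvature additionally requires the absolute
    prominence floor ``CUR_MIN_PROMINENCE``).
    """
    hgd_peaks = detect_peaks(ind.hgd, prominence_frac)
    ria_peaks = detect_peaks(ind.ria, prominence_frac)
    cur_peaks = detect_peaks(
        np.abs(ind.cur), prominence_frac, min_prominence=CUR_MIN_PROMINENCE
    )
    f = (
        hgd_features(ind.hgd, hgd_peaks)
        + ria_features(ind.ria, ria_peaks)
        + sign_change_features(ind.ang, deadband=ANG_DERIV_DEADBAND)
        + polyfit_error_features(ind.ang)
        + sign_change_features(ind.dis, deadband=DIS_DERIV_DEADBAND)
        + polyfit_error_features(ind.dis)
        + cur_features(ind.cur, cur_peaks)
    )
    vec = np.asarray(f, dtype=np.float64)
    assert vec.shape == (24,)
    return vec
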