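"""Synthetic CE+NBI-like test images for the three vascular-pattern classes.

No public corpus of contact-endoscopy NBI frames exists, so the package
ships a generator that emulates the three clinically defined disorder
levels of the superficial vocal-fold vasculature:

* ``order`` — thin, near-parallel vessels (healthy mucosa);
* ``disorder`` — longitudinally wavy vessels (low-grade change);
* ``very_disorder`` — dense high-curvature loops and hooks, the
  appearance of dilated intraepithelial papillary capillary loops
  (IPCLs) seen in malignant change.

Vessels are rendered dark on a bright background (NBI vessels absorb
the narrow-band light), over a smooth illumination trend (low-order 2-D
polynomial plus vignette) that exercises the wavelet detrending stage,
with optical blur and additive Gaussian noise.  Every image also
carries its ground-truth centreline paths.

Each image draws from an RNG seeded by (seed, class, index), so a
dataset is bitwise reproducible and order-independent.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = ["SynthConfig", "SynthImage", "CLASSES",
           "gen_order", "gen_disorder", "gen_very_disorder",
           "gen_image", "iter_images", "gen_dataset"]

CLASSES: tuple[str, ...] = ("order", "disorder", "very_disorder")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.  Amplitudes are fractions of full intensity scale.

    The class-specific geometry (line counts, wave amplitude, loop
    density/radius) is drawn uniformly from the (lo, hi) ranges below.
    """

    image_size: tuple[int, int] = (256, 256)
    n_per_class: int = 100
    seed: int = 7
    vessel_contrast: float = 0.45
    vessel_sigma: float = 1.3          # Gaussian cross-profile width, px
    noise_sd: float = 0.02
    blur_sigma: float = 0.8
    trend_amplitude: float = 0.15
    background: float = 0.8
    # order class
    n_lines: tuple[int, int] = (5, 15)
    line_jitter_deg: float = 3.0
    line_wobble_px: float = 1.0
    # disorder class: heading of the vessel oscillates around the common
    # direction by up to meander_deg, over meander_periods full cycles
    meander_deg: tuple[float, float] = (60.0, 100.0)
    meander_periods: tuple[float, float] = (2.0, 4.0)
    # very_disorder class
    n_loops: tuple[int, int] = (25, 40)
    loop_radius_px: tuple[float, float] = (4.0, 12.0)


@dataclass(frozen=True)
class SynthImage:
    """One generated frame with its label and ground-truth centrelines."""

    image: np.ndarray                       # float in [0, 1]
    label: str
    centerlines: tuple[np.ndarray, ...]     # integer pixel paths, in bounds


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.image_size
    y, x = np.mgrid[0:rows, 0:cols]
    yn = y / (rows - 1) * 2 - 1
    xn = x / (cols - 1) * 2 - 1
    c = rng.uniform(-1, 1, size=6)
    poly = c[0] * yn + c[1] * xn + c[2] * yn * xn + c[3] * yn**2 + c[4] * xn**2 + c[5]
    poly /= max(np.abs(poly).max(), 1e-12)
    vignette = -(yn**2 + xn**2) / 2
    return cfg.background + cfg.trend_amplitude * (0.7 * poly + 0.6 * vignette)


def _render(
    cfg: SynthConfig,
    rng: np.random.Generator,
    curves: list[np.ndarray],
    label: str,
) -> SynthImage:
    """Rasterize float centreline curves into a finished frame."""
    rows, cols = cfg.image_size
    canvas = np.zeros((rows, cols))
    centerlines = []
    for curve in curves:
        inside = (
            (curve[:, 0] >= 0) & (curve[:, 0] <= rows - 1)
            & (curve[:, 1] >= 0) & (curve[:, 1] <= cols - 1)
        )
        curve = curve[inside]
        if len(curve) < 2:
            continue
        px = np.round(curve).astype(int)
        keep = np.concatenate([[True], np.any(np.diff(px, axis=0) != 0, axis=1)])
        px = px[keep]
        canvas[px[:, 0], px[:, 1]] = 1.0
        centerlines.append(px)
    profile = ndimage.gaussian_filter(canvas, cfg.vessel_sigma)
    top = profile.max()
    if top > 0:
        profile /= top
    img = _background(cfg, rng) - cfg.vessel_contrast * profile
    img = ndimage.gaussian_filter(img, cfg.blur_sigma)
    img = img + cfg.noise_sd * rng.standard_normal(img.shape)
    return SynthImage(
        image=np.clip(img, 0.0, 1.0), label=label, centerlines=tuple(centerlines)
    )


def _family_geometry(cfg: SynthConfig, rng: np.random.Generator):
    """Common orientation, per-line normal offsets and parameter grid."""
    rows, cols = cfg.image_size
    diag = float(np.hypot(rows, cols))
    phi = rng.uniform(0.0, np.pi)           # common orientation
    n_lines = rng.integers(cfg.n_lines[0], cfg.n_lines[1] + 1)
    offsets = np.linspace(-diag / 2.4, diag / 2.4, n_lines)
    offsets = offsets + rng.uniform(-0.3, 0.3, n_lines) * np.ptp(offsets) / max(n_lines, 2)
    t = np.arange(-diag / 2, diag / 2, 0.25)
    center = np.array([(rows - 1) / 2, (cols - 1) / 2])
    return phi, offsets, t, center


def gen_order(cfg: SynthConfig, rng: np.random.Generator) -> SynthImage:
    """Thin near-parallel vessels: the 'order' pattern.

    Each line keeps the family orientation up to a few degrees of
    jitter and a ~1 px slow wobble.
    """
    phi, offsets, t, center = _family_geometry(cfg, rng)
    diag = t[-1] - t[0]
    nvec = np.array([-np.cos(phi), np.sin(phi)])
    curves = []
    for off in offsets:
        jitter = np.radians(rng.uniform(-cfg.line_jitter_deg, cfg.line_jitter_deg))
        uj = np.array([np.sin(phi + jitter), np.cos(phi + jitter)])
        nj = np.array([-uj[1], uj[0]])
        phase = rng.uniform(0, 2 * np.pi)
        dev = cfg.line_wobble_px * np.sin(2 * np.pi * t / diag + phase)
        pts = center + off * nvec + t[:, None] * uj + dev[:, None] * nj
        curves.append(pts)
    return _render(cfg, rng, curves, "order")


def gen_disorder(cfg: SynthConfig, rng: np.random.Generator) -> SynthImage:
    """Longitudinally meandering vessels: the 'disorder' pattern.

    The heading of each vessel oscillates sinusoidally about the family
    orientation by 60–100°, so the curve repeatedly swings across its
    mean course the way varicose longitudinal vessels do; the position
    is the integral of the heading.
    """
    phi, offsets, t, center = _family_geometry(cfg, rng)
    diag = t[-1] - t[0]
    nvec = np.array([-np.cos(phi), np.sin(phi)])
    step = float(t[1] - t[0])
    curves = []
    for off in offsets:
        amp = np.radians(rng.uniform(*cfg.meander_deg))
        periods = rng.uniform(*cfg.meander_periods)
        phase = rng.uniform(0, 2 * np.pi)
        psi = phi + amp * np.sin(2 * np.pi * periods * t / diag + phase)
        vel = np.stack([np.sin(psi), np.cos(psi)], axis=1)
        pts = np.cumsum(vel * step, axis=0)
        pts -= pts.mean(axis=0)
        pts += center + off * nvec
        curves.append(pts)
    return _render(cfg, rng, curves, "disorder")


def gen_very_disorder(cfg: SynthConfig, rng: np.random.Generator) -> SynthImage:
    """Dense high-curvature loops and hooks: dilated-IPCL appearance."""
    rows, cols = cfg.image_size
    n_loops = rng.integers(cfg.n_loops[0], cfg.n_loops[1] + 1)
    curves = []
    for _ in range(n_loops):
        r = rng.uniform(*cfg.loop_radius_px)
        cy = rng.uniform(r, rows - 1 - r)
        cx = rng.uniform(r, cols - 1 - r)
        span = rng.uniform(np.pi, 2.2 * np.pi)      # open hooks to closed curls
        start = rng.uniform(0, 2 * np.pi)
        t = np.arange(0.0, span, 0.25 / r)
        ecc = rng.uniform(0.7, 1.3)
        pts = np.stack(
            [cy + r * np.sin(start + t), cx + ecc * r * np.cos(start + t)], axis=1
        )
        curves.append(pts)
    return _render(cfg, rng, curves, "very_disorder")


_GENERATORS = {
    "order": gen_order,
    "disorder": gen_disorder,
    "very_disorder": gen_very_disorder,
}


def _rng_for(cfg: SynthConfig, label: str, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((cfg.seed, CLASSES.index(label), index))
    )


def gen_image(cfg: SynthConfig, label: str, index: int) -> SynthImage:
    """Generate image ``index`` of class ``label`` (deterministic)."""
    if label not in _GENERATORS:
        raise ValueError(f"unknown class label: {label!r}")
    return _GENERATORS[label](cfg, _rng_for(cfg, label, index))


def iter_images(cfg: SynthConfig, classes: tuple[str, ...] = CLASSES):
    """Yield (image id, SynthImage) for the whole configured dataset."""
    for label in classes:
        for i in range(cfg.n_per_class):
            yield f"{label}_{i:04d}", gen_image(cfg, label, i)


def gen_dataset(
    cfg: SynthConfig, out_dir: str | Path, classes: tuple[str, ...] = CLASSES
) -> Path:
    """Write the dataset as 8-bit PNGs plus a manifest CSV.

    Returns the manifest path.  Re-running with the same config
    reproduces identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label", "seed", "index"])
        for image_id, sample in iter_images(cfg, classes):
            fname = f"{image_id}.png"
            iio.imwrite(
                out / fname, np.round(sample.image * 255).astype(np.uint8)
            )
            w.writerow([fname, sample.label, cfg.seed, image_id.rsplit("_", 1)[1]])
    return manifest
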