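"""Shared fixtures and digital-geometry oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from vesselchar.pipeline import extract_features_image
from vesselchar.synthetic import CLASSES, SynthConfig, gen_image


def digital_path(f, tmax: float, n: int = 20000) -> np.ndarray:
    """8-connected digitization of a parametric curve t -> (row, col).

    The curve is sampled densely, rounded to pixels, consecutive
    duplicates dropped, and 4-connected staircase corners compressed to
    diagonal moves — the connectivity a thinning-based skeleton has.
    """
    t = np.linspace(0.0, tmax, n)
    pts = np.round(np.stack(f(t), axis=1)).astype(int)
    keep = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[np.concatenate([[True], keep])]
    out = [pts[0]]
    i = 1
    while i < len(pts):
        if (
            i + 1 < len(pts)
            and np.all(np.abs(pts[i + 1] - out[-1]) <= 1)
            and not np.all(pts[i + 1] == out[-1])
        ):
            i += 1  # staircase corner: jump straight to the diagonal pixel
        out.append(pts[i])
        i += 1
    return np.array(out)


def digital_line(slope: float, length: int = 80) -> np.ndarray:
    return digital_path(lambda t: (slope * t, t), float(length))


def digital_circle(r: float, center: float = 100.0) -> np.ndarray:
    return digital_path(
        lambda t: (center + r * np.sin(t), center + r * np.cos(t)),
        2 * np.pi * 0.999,
    )


@pytest.fixture(scope="session")
def class_features():
    """Feature vectors for 30 images per class at the default settings."""
    cfg = SynthConfig(n_per_class=30)
    out = {}
    for label in CLASSES:
        out[label] = np.array(
            [
                extract_features_image(gen_image(cfg, label, i).image)
                for i in range(cfg.n_per_class)
            ]
        )
    return out


@pytest.fixture(scope="session")
def benchmark_features():
    """The default synthetic 3-class benchmark: 100 images per class,
    256x256, generator seed 7 — the package's stand-in for a clinical
    vascular-pattern dataset."""
    cfg = SynthConfig()
    X, y = [], []
    for label in CLASSES:
        for i in range(cfg.n_per_class):
            X.append(extract_features_image(gen_image(cfg, label, i).image))
            y.append(label)
    return np.array(X), np.array(y)
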