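"""End-to-end plumbing: frame → indicators → feature CSV → evaluation.

The interchange format between extraction and classification is a plain
CSV with columns ``image, label, F1..F24``; evaluation reports are JSON
plus a confusion-matrix CSV.  Per-image extraction failures are logged
and skipped so one corrupt frame cannot abort a batch.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import CLASSIFIER_KINDS, EvalReport, evaluate_cv, grid_search_cv
from .features import FEATURE_NAMES, extract_all
from .indicators import IndicatorConfig, compute_indicators
from .preprocess import PreprocessConfig, preprocess_frame
from .segments import extract_segments
from .synthetic import SynthConfig

__all__ = [
    "PipelineConfig",
    "extract_features_image",
    "run_extract",
    "run_classify",
]

log = logging.getLogger("vesselchar")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations in one serializable document."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    peak_prominence: float = 0.1
    cv_folds: int = 10
    seed: int = 0

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        """Build from a parsed JSON/YAML document; unknown keys rejected."""
        kwargs = {}
        sections = {"preprocess": PreprocessConfig, "indicators": IndicatorConfig,
                    "synth": SynthConfig}
        scalar = {f.name for f in fields(cls)} - set(sections)
        for key, val in doc.items():
            if key in sections:
                known = {f.name for f in fields(sections[key])}
                bad = set(val) - known
                if bad:
                    raise ValueError(f"unknown keys in '{key}': {sorted(bad)}")
                val = {k: tuple(v) if isinstance(v, list) else v for k, v in val.items()}
                kwargs[key] = sections[key](**val)
            elif key in scalar:
                kwargs[key] = val
            else:
                raise ValueError(f"unknown config key: {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


def extract_features_image(
    frame: np.ndarray, config: PipelineConfig | None = None
) -> np.ndarray:
    """Full single-frame pipeline: preprocessing, indicators, 24 features."""
    cfg = config or PipelineConfig()
    processed = preprocess_frame(frame, cfg.preprocess)
    segs = extract_segments(
        processed.skeleton, min_len=cfg.indicators.min_segment_len
    )
    ind = compute_indicators(
        processed.enhanced, processed.filtered, segs, cfg.indicators
    )
    return extract_all(ind, prominence_frac=cfg.peak_prominence)


def run_extract(
    inputs,
    out_csv: str | Path,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Extract the feature table of a batch of images.

    ``inputs`` is an iterable of either image paths or
    ``(image id, 2-D/3-D array, label)`` triples (label may be None for
    paths without a manifest; paths take the label from a sibling
    ``manifest.csv`` when present).  Unreadable images are skipped with
    a warning; zero readable inputs is an error.
    """
    cfg = config or PipelineConfig()
    rows = []
    for item in inputs:
        if isinstance(item, (str, Path)):
            path = Path(item)
            image_id, label = path.stem, _manifest_label(path)
            try:
                frame = iio.imread(path)
            except Exception as exc:  # pragma: no cover - exercised via tests
                log.warning("skipping unreadable image %s: %s", path, exc)
                continue
        else:
            image_id, frame, label = item
        t0 = time.perf_counter()
        try:
            vec = extract_features_image(np.asarray(frame), cfg)
        except Exception as exc:
            log.warning("feature extraction failed for %s: %s", image_id, exc)
            continue
        log.debug("extracted %s in %.2fs", image_id, time.perf_counter() - t0)
        rows.append([image_id, label, *vec])
    if not rows:
        raise ValueError("no readable input images")
    df = pd.DataFrame(rows, columns=["image", "label", *FEATURE_NAMES])
    df.to_csv(out_csv, index=False, float_format="%.12g")
    return df


def _manifest_label(path: Path) -> str | None:
    manifest = path.parent / "manifest.csv"
    if not manifest.exists():
        return None
    table = pd.read_csv(manifest)
    hit = table.loc[table["filename"] == path.name, "label"]
    return None if hit.empty else str(hit.iloc[0])


def load_feature_table(csv_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a feature CSV into (X, y); requires the label column filled."""
    try:
        df = pd.read_csv(csv_path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature CSV {csv_path}: {exc}") from exc
    missing = [c for c in ("label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {csv_path} lacks columns: {missing}")
    if df["label"].isna().any():
        raise ValueError(f"feature CSV {csv_path} has rows without a label")
    return df[list(FEATURE_NAMES)].to_numpy(float), df["label"].to_numpy(str)


def run_classify(
    csv_path: str | Path,
    out_dir: str | Path,
    kinds=CLASSIFIER_KINDS,
    grid_search: bool = False,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Evaluate classifiers on a feature CSV; write JSON + confusion CSVs."""
    X, y = load_feature_table(csv_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = {}
    for kind in kinds:
        params = (
            grid_search_cv(X, y, kind, seed=seed, folds=folds)
            if grid_search
            else None
        )
        rep = evaluate_cv(X, y, kind, params=params, seed=seed, folds=folds)
        reports[kind] = rep
        (out / f"report_{kind}.json").write_text(rep.to_json(indent=2) + "\n")
        pd.DataFrame(
            rep.confusion, index=list(rep.classes), columns=list(rep.classes)
        ).to_csv(out / f"confusion_{kind}.csv")
    return reports
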