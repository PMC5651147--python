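"""Declarative pipeline configuration, run manifests, and click files."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline in one document.

    Unknown keys and out-of-range values are rejected at load time with
    the offending key path.
    """

    # phantom generation
    n_vertebrae: int = 17
    slope_min: float = 5.0
    slope_max: float = 50.0
    mean_slope_magnitude: float = 15.0
    curve_family: str = "single_curve"
    noise_level: float = 5.0
    # patch pipeline
    patch_size: int = 150
    downsampled_size: int = 50
    patches_per_vertebra: int = 100
    jitter_radius: float = 15.0
    # network
    h2_size: int = 500
    h3_size: int = 50
    pretrain_learning_rate: float = 0.1
    pretrain_epochs: int = 20
    finetune_learning_rate: float = 0.01
    finetune_epochs: int = 50
    batch_size: int = 128
    # reliability simulation
    click_noise_sd: float = 5.0
    sessions: int = 2
    # randomness
    seed: int = 0

    _RANGES = {
        "n_vertebrae": (2, 30),
        "slope_min": (0.0, 89.0),
        "slope_max": (0.0, 89.0),
        "mean_slope_magnitude": (0.1, 89.0),
        "noise_level": (0.0, 100.0),
        "patch_size": (150, 150),
        "downsampled_size": (50, 50),
        "patches_per_vertebra": (1, 10**6),
        "jitter_radius": (0.0, 75.0),
        "h2_size": (1, 10**5),
        "h3_size": (1, 10**5),
        "pretrain_learning_rate": (1e-8, 10.0),
        "pretrain_epochs": (1, 10**6),
        "finetune_learning_rate": (1e-8, 10.0),
        "finetune_epochs": (1, 10**6),
        "batch_size": (1, 10**6),
        "click_noise_sd": (0.0, 100.0),
        "sessions": (2, 100),
        "seed": (0, 2**31 - 1),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValidationError(
                    f"config key '{name}': value {val} outside [{lo}, {hi}]"
                )
        if self.slope_min >= self.slope_max:
            raise ValidationError(
                "config key 'slope_min': must be < slope_max"
            )
        if self.curve_family not in ("single_curve", "double_curve"):
            raise ValidationError(
                f"config key 'curve_family': unknown family "
                f"{self.curve_family!r}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config document; missing keys take their defaults,
    unknown keys are rejected with the key path."""
    doc = {}
    if path is not None:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: config must be a mapping")
    if overrides:
        doc.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    cfg = PipelineConfig(**doc)
    cfg.validate()
    return cfg


def read_clicks(path) -> list[tuple[float, float]]:
    """Read user clicks from a CSV with header ``x,y`` (0-based pixel
    coordinates, one vertebra per row; any common CSV dialect)."""
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except Exception as exc:
        raise ValidationError(f"cannot parse clicks file {path}: {exc}")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not {"x", "y"} <= set(df.columns):
        raise ValidationError(f"{path}: clicks CSV needs 'x' and 'y' columns")
    if len(df) < 2:
        raise ValidationError(
            f"{path}: need >= 2 clicked vertebrae, got {len(df)}"
        )
    try:
        xs = df["x"].astype(float)
        ys = df["y"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric click coordinate: {exc}")
    if xs.isna().any() or ys.isna().any():
        raise ValidationError(f"{path}: non-numeric click coordinate")
    return list(zip(xs.tolist(), ys.tolist()))


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path,
    command: str,
    config: PipelineConfig,
    seeds: dict,
    inputs: list | None = None,
    outputs: list | None = None,
) -> dict:
    """Emit the run manifest: config snapshot, software version, seeds,
    input digests, output list, timestamp."""
    from . import __version__

    manifest = {
        "command": command,
        "software_version": __version__,
        "config": config.to_dict(),
        "seeds": seeds,
        "inputs": [
            {"path": str(p), "sha256": file_digest(p)} for p in (inputs or [])
        ],
        "outputs": [str(p) for p in (outputs or [])],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
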