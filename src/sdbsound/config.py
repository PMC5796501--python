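"""Run configuration: flat dotted keys, YAML file + CLI overrides, manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: every recognized configuration key and its default
DEFAULTS: dict[str, object] = {
    "seed": 0,
    "preprocess.fft_ms": 32.0,
    "preprocess.hop_ms": 16.0,
    "preprocess.frac_quietest": 0.1,
    "preprocess.oversubtraction": 2.0,
    "preprocess.floor": 0.02,
    "preprocess.keep_stages": ["N2", "N3"],
    "preprocess.epoch_seconds": 30.0,
    "features.window_s": 5.0,
    "features.frame_ms": 32.0,
    "features.n_mfcc": 13,
    "features.lpc_order": 10,
    "features.spl_floor_db": -120.0,
    "features.calibration_offset": 0.0,
    "qtm.frame_s": 1.0,
    "qtm.silence_quantile": 0.15,
    "qtm.high_quantile": 0.85,
    "qtm.apnea_min_s": 20.0,
    "qtm.apnea_max_s": 60.0,
    "select.alpha": 0.05,
    "select.require_anova": True,
    "select.top_k": 50,
    "classify.classifier": "logistic",
    "classify.features": "biomarker+qtm",
    "classify.task": "four_group",
    "classify.threshold": 15.0,
    "classify.folds": 10,
    "classify.refit_selection": False,
}


@dataclass
class RunConfig:
    """Validated flat configuration; unknown keys are rejected."""

    values: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def load(cls, path: str | Path | None, overrides: dict[str, object] | None = None) -> "RunConfig":
        values: dict[str, object] = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping of dotted keys")
            values.update(loaded)
        if overrides:
            values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(values=values)

    def manifest(self, extra: dict | None = None) -> dict:
        from sdbsound import __version__

        out = {"config": dict(self.values), "version": __version__}
        if extra:
            out.update(extra)
        return out

    def save_manifest(self, path: str | Path, extra: dict | None = None) -> None:
        Path(path).write_text(json.dumps(self.manifest(extra), indent=1, default=str))
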