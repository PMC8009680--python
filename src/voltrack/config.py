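"""Run configuration: YAML loading, validation, mapping onto parameters.

A configuration file mirrors the pipeline's parameter tables: the
preprocessing noise level, the minimum cell size for the watershed, and the
registration's coherence knobs (beta, lambda, maximum iteration).  Unknown
keys are rejected, and all validation failures are reported at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessParams
from .registration import RegistrationParams
from .segment import SegmentParams
from .tracker import TrackerConfig

_SCHEMA = {
    "seed": int,
    "output_dir": str,
    "spacing": list,
    "preprocess": {"noise_level": float, "window": list, "enabled": bool},
    "segment": {
        "backend": str,
        "min_cell_size": int,
        "prob_threshold": float,
        "blur_sigma": float,
        "patch_shape": list,
        "epochs": int,
        "base_channels": int,
    },
    "track": {
        "mode": str,
        "beta": float,
        "lambda": float,
        "max_iter": int,
        "rematch_every": int,
        "outlier_weight": float,
        "ensemble_max_refs": int,
        "correction_max_iter": int,
        "correction_tol": float,
        "interpolate_z": bool,
        "skip_volumes": list,
    },
    "ffn": {"n_pairs": int, "epochs": int, "batch_size": int},
    "scene": {
        "n_cells": int,
        "volume_shape": list,
        "spacing": list,
        "cell_radius": list,
        "deformation_amplitude": float,
        "deformation_coherence_length": float,
        "intensity_cell": float,
        "intensity_bg": float,
        "photobleach_rate": float,
        "n_volumes": int,
        "shot_noise": bool,
    },
}


@dataclass
class RunConfig:
    raw: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "out"
    spacing: tuple = (1.5, 0.5, 0.5)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        errors = _validate(d, _SCHEMA, prefix="")
        if errors:
            raise ValueError(
                "invalid configuration:\n  " + "\n  ".join(errors)
            )
        cfg = cls(raw=d)
        cfg.seed = int(d.get("seed", 0))
        cfg.output_dir = str(d.get("output_dir", "out"))
        cfg.spacing = tuple(d.get("spacing", (1.5, 0.5, 0.5)))
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    # -- parameter blocks --------------------------------------------------
    def preprocess_params(self) -> PreprocessParams:
        p = self.raw.get("preprocess", {})
        params = PreprocessParams()
        if "noise_level" in p:
            params.noise_level = float(p["noise_level"])
        if "window" in p:
            params.window = tuple(int(v) for v in p["window"])
        return params

    def segment_params(self) -> SegmentParams:
        s = self.raw.get("segment", {})
        params = SegmentParams()
        if "min_cell_size" in s:
            params.min_cell_size = int(s["min_cell_size"])
        if "prob_threshold" in s:
            params.prob_threshold = float(s["prob_threshold"])
        if "blur_sigma" in s:
            params.blur_sigma = float(s["blur_sigma"])
        return params

    def registration_params(self) -> RegistrationParams:
        t = self.raw.get("track", {})
        params = RegistrationParams()
        if "beta" in t:
            params.beta = float(t["beta"])
        if "lambda" in t:
            params.lam = float(t["lambda"])
        if "max_iter" in t:
            params.max_iter = int(t["max_iter"])
        if "rematch_every" in t:
            params.rematch_every = int(t["rematch_every"])
        if "outlier_weight" in t:
            params.outlier_weight = float(t["outlier_weight"])
        return params

    def tracker_config(self) -> TrackerConfig:
        t = self.raw.get("track", {})
        cfg = TrackerConfig(
            preprocess=self.preprocess_params(),
            segment=self.segment_params(),
            registration=self.registration_params(),
        )
        cfg.mode = t.get("mode", "single")
        if "ensemble_max_refs" in t:
            cfg.ensemble_max_refs = int(t["ensemble_max_refs"])
        if "correction_max_iter" in t:
            cfg.correction_max_iter = int(t["correction_max_iter"])
        if "correction_tol" in t:
            cfg.correction_tol = float(t["correction_tol"])
        if "interpolate_z" in t:
            cfg.interpolate_z = bool(t["interpolate_z"])
        if "skip_volumes" in t:
            cfg.skip_volumes = tuple(int(v) for v in t["skip_volumes"])
        pre = self.raw.get("preprocess", {})
        if "enabled" in pre:
            cfg.use_preprocess = bool(pre["enabled"])
        cfg.validate()
        return cfg

    def scene_params(self):
        from .synthetic import SceneParams

        s = dict(self.raw.get("scene", {}))
        params = SceneParams(seed=self.seed)
        for key, val in s.items():
            if key in ("volume_shape", "spacing", "cell_radius"):
                val = tuple(val)
            setattr(params, key, val)
        params.validate()
        return params


def _validate(d: dict, schema: dict, prefix: str) -> list[str]:
    errors = []
    if not isinstance(d, dict):
        return [f"{prefix or 'config'}: expected a mapping"]
    for key, val in d.items():
        if key not in schema:
            errors.append(f"unknown key: {prefix}{key}")
            continue
        expected = schema[key]
        if isinstance(expected, dict):
            errors.extend(_validate(val or {}, expected, prefix=f"{prefix}{key}."))
        elif expected in (float, int):
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                errors.append(f"{prefix}{key}: expected a number, got {val!r}")
        elif expected is bool:
            if not isinstance(val, bool):
                errors.append(f"{prefix}{key}: expected a boolean, got {val!r}")
        elif expected is list:
            if not isinstance(val, (list, tuple)):
                errors.append(f"{prefix}{key}: expected a list, got {val!r}")
        elif expected is str:
            if not isinstance(val, str):
                errors.append(f"{prefix}{key}: expected a string, got {val!r}")
    return errors
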