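"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    The master ``seed`` is mandatory: every random draw (fold assignment,
    permutations, subgroup folds) descends from it, so a config + seed pair
    pins the run down completely.
    """

    # inputs
    abundances: str = ""
    covariates: str = ""
    clinical: str = ""
    images: str = ""  # glob pattern, one NIfTI per subject
    mask: str = ""  # optional NIfTI mask; empty -> derive from mean image
    outdir: str = "gutbrainmap_run"
    # preprocessing
    floor: float = 1e-3
    min_subject_frac: float = 0.05
    min_ra: float = 0.01
    mask_threshold_frac: float = 0.1
    # association
    k_folds: int = 10
    lambda_min: float = 1e-3
    lambda_max: float = 1e3
    lambda_num: int = 20
    lambda_rule: str = "gcv"
    # inference
    perm_scheme: str = "orthogonal"  # or "freedman_lane"
    n_perms: int = 250
    stage_perms: int = 0  # if >0, run this many first, then extend to n_perms
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float | None = None
    connectivity: int = 26
    # reporting thresholds
    fwe_alpha: float = 0.05
    uncorrected_p: float = 0.004
    min_ratio: float = 1.33
    # randomness
    seed: int | None = None
    # subgroup definitions: name -> pandas query over covariate/clinical columns
    subgroups: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.seed is None:
            raise ConfigError("seed is mandatory (no silent nondeterminism)")
        for name in ("fwe_alpha", "uncorrected_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name}={v} must be in (0, 1]")
        if self.floor <= 0:
            raise ConfigError(f"floor={self.floor} must be positive")
        if self.n_perms < 1:
            raise ConfigError("n_perms must be at least 1")
        if self.stage_perms < 0 or self.stage_perms > self.n_perms:
            raise ConfigError("stage_perms must be in [0, n_perms]")
        if self.k_folds < 2:
            raise ConfigError("k_folds must be at least 2")
        return self

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.lambda_min), np.log10(self.lambda_max), self.lambda_num)

    def tfce_params(self):
        from .inference import TfceParams

        return TfceParams(E=self.tfce_e, H=self.tfce_h, dh=self.tfce_dh, connectivity=self.connectivity)

    def thresholds(self):
        from .inference import ClusterThresholds

        return ClusterThresholds(
            fwe_alpha=self.fwe_alpha, uncorrected_p=self.uncorrected_p, min_ratio=self.min_ratio
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def override(self, assignments: list[str]) -> "RunConfig":
        """Apply ``key=value`` overrides (CLI); values parsed as YAML scalars."""
        d = self.to_dict()
        for a in assignments:
            if "=" not in a:
                raise ConfigError(f"override {a!r} is not of the form key=value")
            key, _, val = a.partition("=")
            if key not in d:
                raise ConfigError(f"unknown config key {key!r}")
            d[key] = yaml.safe_load(val)
        return type(self).from_dict(d)


def resolve_image_paths(pattern: str) -> list[Path]:
    import glob

    paths = sorted(glob.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no images match pattern {pattern!r}")
    return [Path(p) for p in paths]
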