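"""Run configuration: defaults, validation, and per-stage seed derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .design import ValidationError

_STAGES = (
    "simulate",
    "qc",
    "anova_nonstressed",
    "anova_stressed",
    "cluster",
    "respond",
    "two_group",
    "phenotype",
)


@dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    Every stage seed is derived deterministically from ``seed`` so one
    integer reproduces the whole run.
    """

    # paths (unused when simulate=True)
    counts: str | None = None
    design: str | None = None
    phenotype: str | None = None
    standards: str | None = None
    out_dir: str = "acclimkit_run"
    # orchestration
    simulate: bool = False
    seed: int = 0
    # stage parameters
    min_mean: float = 5.0
    pseudocount: float = 1.0
    z_threshold: float = 3.0
    alpha: float = 0.01
    n_permutations: int = 999
    rho_threshold: float = 0.6
    min_cluster_size: int = 10
    n_draws: int = 1000
    dampening_stratum: str = "day == 11"
    tau_baseline: float = 0.5
    tau_response: float = 0.25
    exclude_day0: bool = True
    two_group_alpha: float = 0.05
    # generator overrides (passed to GeneratorConfig when simulating)
    generator: dict = field(default_factory=dict)
    inject_artifact: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.two_group_alpha < 1:
            raise ValidationError(
                f"two_group_alpha must be in (0, 1), got {self.two_group_alpha}"
            )
        if self.n_permutations < 99:
            raise ValidationError(
                f"n_permutations must be >= 99, got {self.n_permutations}"
            )
        if self.n_draws < 999:
            raise ValidationError(f"n_draws must be >= 999, got {self.n_draws}")
        if not 0 < self.rho_threshold < 1:
            raise ValidationError(
                f"rho_threshold must be in (0, 1), got {self.rho_threshold}"
            )
        if self.min_cluster_size < 2:
            raise ValidationError("min_cluster_size must be >= 2")
        if not self.simulate:
            for name in ("counts", "design"):
                if getattr(self, name) is None:
                    raise ValidationError(
                        f"config requires {name!r} path unless simulate=true"
                    )

    def stage_seed(self, stage: str) -> int:
        """Deterministic sub-seed (< 2^31) for a named stage."""
        if stage not in _STAGES:
            raise ValidationError(f"unknown stage {stage!r}; stages: {_STAGES}")
        state = np.random.SeedSequence(int(self.seed)).generate_state(len(_STAGES))
        return int(state[_STAGES.index(stage)] % (2**31))


def validate_config(raw: dict | None, **overrides) -> RunConfig:
    """Build a RunConfig from a raw mapping, rejecting unknown keys."""
    raw = dict(raw or {})
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {unknown}")
    return RunConfig(**raw)


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML config file and validate it."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return validate_config(raw, **overrides)
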