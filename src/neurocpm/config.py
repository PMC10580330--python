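"""Run configuration with study defaults and per-stage seed derivation."""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters (defaults are the study's printed settings) and paths.

    threshold_p: edge-selection p threshold (0.01); fd_threshold: scrubbing
    threshold in mm (0.2, removal at FD >= threshold); min_volumes: minimum
    retained volumes for inclusion (120); n_perm: permutation count (1000);
    covariates: subject-table columns controlled during selection;
    ard_cutoff / td_cutoff: subtype ratio cutoffs (0.8 / 1.0).
    """

    threshold_p: float = 0.01
    fd_threshold: float = 0.2
    min_volumes: int = 120
    n_perm: int = 1000
    covariates: tuple[str, ...] = ("age", "gender", "duration_years")
    ard_cutoff: float = 0.8
    td_cutoff: float = 1.0
    score: str = "score_ar"
    seed: int = 0
    # paths (optional; used by the CLI pipeline)
    subject_table: str | None = None
    matrices_dir: str | None = None
    atlas_path: str | None = None
    output_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Derived per-stage seed: stable hash of the stage name folded into
        the global seed, independent of stage execution order."""
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in d and d["covariates"] is not None:
            d = {**d, "covariates": tuple(d["covariates"])}
        return cls(**d)

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return replace(self, **kwargs)
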