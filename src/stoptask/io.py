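"""Run configuration and file schemas.

Single interchange format: tidy long CSV (UTF-8, empty fields for
non-applicable values). Schedules carry integer milliseconds; simulated RTs
and SSDs are reals. All randomness in a run flows from one integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .design import DesignSpec, default_design
from .simulate import (
    GroupParamSpec,
    PARAM_COLUMNS,
    TRIAL_LOG_COLUMNS,
    default_group_specs,
)

log = logging.getLogger("stoptask")

TRIAL_LOG_SCHEMA_VERSION = 1
SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Serializable configuration of a simulate/analyze run."""

    seed: int = 0
    n_per_group: int = 14
    design: DesignSpec = field(default_factory=default_design)
    group_specs: tuple[GroupParamSpec, ...] = field(default_factory=default_group_specs)
    copula_target: float | None = -0.47
    output_dir: str = "."
    run_anova: bool = True

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_group": self.n_per_group,
            "design": self.design.to_dict(),
            "group_specs": [asdict(g) for g in self.group_specs],
            "copula_target": self.copula_target,
            "output_dir": self.output_dir,
            "run_anova": self.run_anova,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = DesignSpec.from_dict(d["design"])
        if "group_specs" in d:
            d["group_specs"] = tuple(GroupParamSpec(**g) for g in d["group_specs"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def write_trial_log(trials: pd.DataFrame, path) -> None:
    trials.loc[:, TRIAL_LOG_COLUMNS].to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path}: missing columns {missing}")
    bad = df["outcome"].isna()
    if bad.any():
        raise ValueError(f"trial log {path}: empty outcome at row {int(bad.idxmax())}")
    return df[TRIAL_LOG_COLUMNS]


def write_params(params: pd.DataFrame, path) -> None:
    params.to_csv(path, index=False)


def read_params(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"params file {path}: missing column 'subject_id'")
    return df
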