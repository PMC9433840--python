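"""Dataset and report I/O, run configuration, provenance headers.

Trial logs travel as CSV with a fixed column schema; every file written
here carries a comment header embedding the run seed and a hash of the
configuration, so outputs are traceable to the exact settings that
produced them. Run configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import DATASET_COLUMNS, OthersDistribution
from .task import DEFAULT_CONFIG, TaskConfig, replenish

__all__ = [
    "RunConfig",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "write_table",
    "write_report",
]

_INT_COLUMNS = [
    "session", "trial", "stock_pre", "own_choice", "own_payoff",
    "other1_catch", "other2_catch", "outflow", "stock_post_catch", "stock_next",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full pipeline run; serializes losslessly to YAML."""

    task: TaskConfig = DEFAULT_CONFIG
    others_distribution: OthersDistribution = field(default_factory=OthersDistribution)
    models: tuple[str, ...] = ("null", "social", "nonsocial", "rw", "fs")
    n_starts: int = 20
    drop_last_trial: bool = False
    seed: int = 0
    bms_mc_samples: int = 1_000_000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["task"]["net_sizes"] = list(self.task.net_sizes)
        d["others_distribution"]["support"] = list(self.others_distribution.support)
        d["others_distribution"]["probabilities"] = list(
            self.others_distribution.probabilities
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        task = d.pop("task", {})
        dist = d.pop("others_distribution", {})
        return cls(
            task=TaskConfig(**{**task, "net_sizes": tuple(task.get("net_sizes", (1, 2, 3)))}),
            others_distribution=OthersDistribution(
                support=tuple(dist.get("support", (2, 3, 4, 5, 6))),
                probabilities=tuple(
                    dist.get("probabilities", (0.034, 0.027, 0.349, 0.253, 0.337))
                ),
            ),
            models=tuple(d.pop("models", ("null", "social", "nonsocial", "rw", "fs"))),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class DatasetValidationError(ValueError):
    pass


def _provenance_header(config: RunConfig | None, seed: int | None) -> str:
    h = config.hash() if config is not None else "none"
    return f"# cprlearn config_hash={h} seed={seed}\n"


def write_dataset(
    dataset: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a trial log as CSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, seed))
        dataset.to_csv(fh, index=False)


def read_dataset(
    path: str | Path,
    config: TaskConfig = DEFAULT_CONFIG,
    validate: bool = True,
) -> pd.DataFrame:
    """Read and validate a behavioral trial log.

    Checks the column schema, integer catches, choice codes, condition
    labels, and the stock-evolution consistency
    stock_next = replenish(stock_post_catch); violations are reported with
    the offending CSV line number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing columns {missing}")
    df = df[DATASET_COLUMNS]
    if not validate:
        return df
    # line numbers: header row is line 1 (+1 if a comment header precedes it)
    offset = 3 if _has_comment_header(path) else 2

    for col in _INT_COLUMNS:
        vals = df[col]
        bad = vals.isna() | (vals != vals.astype(int))
        if bad.any():
            i = int(bad.idxmax())
            raise DatasetValidationError(
                f"{path} line {i + offset}: non-integer {col}={vals.iloc[i]}"
            )
        df[col] = vals.astype(int)
    bad = ~df["own_choice"].isin(config.net_sizes)
    if bad.any():
        i = int(bad.idxmax())
        raise DatasetValidationError(
            f"{path} line {i + offset}: own_choice={df['own_choice'].iloc[i]} "
            f"not in {config.net_sizes}"
        )
    bad = ~df["condition"].isin(["social", "nonsocial"])
    if bad.any():
        i = int(bad.idxmax())
        raise DatasetValidationError(
            f"{path} line {i + offset}: unknown condition {df['condition'].iloc[i]!r}"
        )
    expected = df["stock_post_catch"].map(lambda s: replenish(int(s), config))
    bad = df["stock_next"] != expected
    if bad.any():
        i = int(bad.idxmax())
        raise DatasetValidationError(
            f"{path} line {i + offset}: stock_next={df['stock_next'].iloc[i]} "
            f"inconsistent with replenish(stock_post_catch="
            f"{df['stock_post_catch'].iloc[i]})"
        )
    df["terminal"] = df["terminal"].astype(bool)
    return df


def _has_comment_header(path: Path) -> bool:
    with open(path) as fh:
        return fh.readline().startswith("#")


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    sep: str = ",",
) -> None:
    """Write any tabular result as CSV/TSV with a provenance header."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(config, seed))
        table.to_csv(fh, index=False, sep=sep)


def write_report(
    report: dict,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write a JSON report with provenance fields embedded."""
    payload = {
        "config_hash": config.hash() if config is not None else None,
        "seed": seed,
        **report,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
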