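"""CSV / config readers and writers plus run manifests.

Conventions: comma-separated UTF-8 CSV with a header row; floats written
with 17 significant digits so values round-trip bit-exactly; a missing
exposure is an empty field on disk and NaN in memory.  A non-finite bias
ratio is serialized as the literal ``inf``/``-inf`` (parseable by
``float``), never as an empty or NaN cell.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bias import BiasReport
from .exceptions import SchemaError
from .montecarlo import MCSummary
from .twostage import TwoStageResult

__all__ = [
    "SURVIVAL_SCHEMA",
    "APPLIED_SCHEMA",
    "read_cohort",
    "write_cohort",
    "write_results",
    "load_config",
    "save_config",
    "RunManifest",
]

FLOAT_FORMAT = "%.17g"

#: required columns of the abstract survival cohort
SURVIVAL_SCHEMA = ("x", "z1", "z2", "y", "D", "time", "event")
#: required columns of the applied blood-pressure cohort
APPLIED_SCHEMA = ("age", "male", "overweight", "D", "sbp")


def read_cohort(path, schema=SURVIVAL_SCHEMA) -> pd.DataFrame:
    """Read a cohort CSV, enforcing the expected columns.

    ``schema`` is the tuple of required column names.  Empty cells in the
    exposure column (or any column) become NaN; any non-numeric cell raises
    :class:`SchemaError` naming the column and row index.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing} "
            f"(found {list(df.columns)})"
        )
    for col in schema:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        df[col] = parsed
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV (17-significant-digit floats, NaN as empty)."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, na_rep="")


def _bias_frame(report: BiasReport) -> pd.DataFrame:
    def fmt(v):
        return v if v is not None else np.nan

    bias = report.bias if report.finite else float(np.sign(report.delta) or 1) * np.inf
    expected = report.expected_estimate
    if report.theta is not None and not report.finite:
        expected = bias
    return pd.DataFrame(
        [
            {
                "delta": report.delta,
                "d": report.d,
                "bias": bias,
                "finite": report.finite,
                "theta": fmt(report.theta),
                "expected_estimate": fmt(expected),
            }
        ]
    )


def write_results(result, path) -> Path:
    """Serialize a result object to CSV with a stable column order.

    Dispatches on type: :class:`BiasReport` (one row),
    :class:`TwoStageResult` (per-term Stage II table) or
    :class:`MCSummary` (per-term replication summary).  Returns the path
    written.
    """
    path = Path(path)
    if isinstance(result, BiasReport):
        _bias_frame(result).to_csv(path, index=False,
                                   float_format=FLOAT_FORMAT)
    elif isinstance(result, TwoStageResult):
        result.stage2.to_csv(path, float_format=FLOAT_FORMAT)
    elif isinstance(result, MCSummary):
        out = result.table.copy()
        out["n_reps"] = result.n_reps
        out["n_failed"] = result.n_failed
        out.to_csv(path, float_format=FLOAT_FORMAT)
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    else:
        raise TypeError(f"cannot serialize result of type {type(result)!r}")
    return path


def read_mcsummary(path) -> MCSummary:
    """Reload an :class:`MCSummary` table written by :func:`write_results`."""
    df = pd.read_csv(path, index_col="term")
    n_reps = int(df.pop("n_reps").iloc[0])
    n_failed = int(df.pop("n_failed").iloc[0])
    return MCSummary(table=df, n_reps=n_reps, n_failed=n_failed)


def load_config(path) -> dict:
    """Load a flat key-value parameter file (YAML; JSON is valid YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: expected a flat mapping of parameters")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one CLI run: version, config, seed, outputs."""

    command: str
    config: dict
    seed: int = None
    outputs: list = dataclasses.field(default_factory=list)
    version: str = __version__
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        return path
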