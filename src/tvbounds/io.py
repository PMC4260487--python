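"""Readers and writers for the package's CSV/JSON artifacts.

All times are in seconds, step indices are 1-based, and floating-point
output carries 12 significant digits so write-then-read round trips are
lossless for practical purposes.  Readers validate schema and values and
report offending line numbers (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .empirical import RTDataset
from .types import BoundaryPair, ChoiceRTDistribution

__all__ = [
    "ValidationError",
    "read_boundaries",
    "write_boundaries",
    "read_distribution",
    "write_distribution",
    "read_rt_data",
    "write_rt_data",
    "load_config",
    "write_resolved_config",
]

_FLOAT_FMT = "%.12g"


class ValidationError(ValueError):
    """A file violated the expected schema; the message carries line numbers."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing} (found {list(df.columns)})")


def _check(cond: np.ndarray, path, message: str) -> None:
    bad = np.nonzero(~np.asarray(cond))[0]
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        more = "" if bad.size <= 5 else f" (+{bad.size - 5} more)"
        raise ValidationError(f"{path}: {message} at line(s) {lines}{more}")


# -- boundaries -------------------------------------------------------------

def write_boundaries(bounds: BoundaryPair, path) -> None:
    df = pd.DataFrame(
        {
            "step_index": np.arange(0, bounds.n_steps + 1),
            "time_s": np.concatenate(([0.0], bounds.times)),
            "upper": np.concatenate(([bounds.start_upper], bounds.upper)),
            "lower": np.concatenate(([bounds.start_lower], bounds.lower)),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_boundaries(path) -> BoundaryPair:
    df = pd.read_csv(path)
    _require_columns(df, ("step_index", "time_s", "upper", "lower"), path)
    df = df.sort_values("step_index").reset_index(drop=True)
    t = df["time_s"].to_numpy(float)
    _check(np.diff(t) > 0, path, "non-monotone time_s")
    if int(df["step_index"].iloc[0]) == 0:
        start_u, start_l = float(df["upper"].iloc[0]), float(df["lower"].iloc[0])
        df = df.iloc[1:]
        step = float(t[1] - t[0])
    else:
        step = float(t[0])
        start_u, start_l = float(df["upper"].iloc[0]), float(df["lower"].iloc[0])
    return BoundaryPair(
        df["upper"].to_numpy(float), df["lower"].to_numpy(float), start_u, start_l, step
    )


# -- choice/RT distributions ------------------------------------------------

def write_distribution(dist: ChoiceRTDistribution, path) -> None:
    df = pd.DataFrame(
        {
            "step_index": np.arange(1, dist.n_steps + 1),
            "time_s": dist.times,
            "p_step_upper": dist.pmf_upper,
            "p_step_lower": dist.pmf_lower,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_distribution(path) -> ChoiceRTDistribution:
    df = pd.read_csv(path)
    _require_columns(df, ("step_index", "time_s", "p_step_upper", "p_step_lower"), path)
    df = df.sort_values("step_index").reset_index(drop=True)
    t = df["time_s"].to_numpy(float)
    _check(np.diff(t) > 0, path, "non-monotone time_s")
    for col in ("p_step_upper", "p_step_lower"):
        _check(df[col].to_numpy(float) >= 0, path, f"negative probability in {col}")
    step = float(t[0]) if len(t) == 1 else float(np.median(np.diff(t)))
    return ChoiceRTDistribution(
        df["p_step_upper"].to_numpy(float), df["p_step_lower"].to_numpy(float), step
    )


# -- raw RT data ------------------------------------------------------------

def write_rt_data(data: RTDataset, path) -> None:
    df = pd.DataFrame(
        {
            "subject": data.subject,
            "condition": data.condition,
            "choice": data.choice,
            "rt_s": data.rt,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_rt_data(path, subject: str | None = None, condition: str | None = None) -> RTDataset:
    df = pd.read_csv(path)
    _require_columns(df, ("subject", "condition", "choice", "rt_s"), path)
    _check(df["rt_s"].to_numpy(float) > 0, path, "non-positive rt_s")
    _check(df["choice"].isin(["A", "B"]).to_numpy(), path, "choice label not in {A, B}")
    if subject is not None:
        df = df[df["subject"] == subject]
    if condition is not None:
        df = df[df["condition"] == condition]
    if df.empty:
        raise ValidationError(f"{path}: no records after subject/condition filtering")
    subj = str(df["subject"].iloc[0]) if df["subject"].nunique() == 1 else "mixed"
    cond = str(df["condition"].iloc[0]) if df["condition"].nunique() == 1 else "mixed"
    return RTDataset(
        rt=df["rt_s"].to_numpy(float),
        choice=df["choice"].to_numpy(object),
        subject=subj,
        condition=cond,
    )


# -- run configuration ------------------------------------------------------

def load_config(path) -> dict[str, Any]:
    """Flat key-value YAML config; nested documents are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a flat mapping")
    for key, value in doc.items():
        if isinstance(value, (dict, list)):
            raise ValidationError(f"{path}: config key {key!r} is nested; flat values only")
    return doc


def write_resolved_config(config: dict[str, Any], out_prefix) -> Path:
    """Echo the fully-resolved configuration as JSON next to the outputs."""
    path = Path(f"{out_prefix}.config.json")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
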