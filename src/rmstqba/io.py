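"""Cohort CSV reading/writing, run manifests and config files.

The cohort schema is comma-separated UTF-8 with a header and required columns
``time`` (months, nonnegative float), ``event`` (0/1) and ``arm`` (0/1);
optional columns ``u_true`` and any number of covariate columns are
recognised. Validation errors name the offending row (1-based data rows) and
column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .model_core import Coding, Cohort

__all__ = ["read_cohort", "write_cohort", "write_manifest", "load_config"]

REQUIRED_COLUMNS = ("time", "event", "arm")


def read_cohort(path: str | Path, coding: Coding = Coding.ZERO_ONE) -> Cohort:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col, ok in (
        ("time", lambda s: (s >= 0) & np.isfinite(s)),
        ("event", lambda s: s.isin([0, 1])),
        ("arm", lambda s: s.isin([0, 1])),
    ):
        valid = ok(df[col])
        if not valid.all():
            row = int(valid.idxmin()) + 1
            raise ValueError(
                f"{path}: invalid value in column {col!r} at data row {row} "
                f"(got {df[col].iloc[row - 1]!r})"
            )
    u_true = None
    if "u_true" in df.columns:
        lo, hi = coding.levels
        valid = df["u_true"].isin([lo, hi])
        if not valid.all():
            row = int(valid.idxmin()) + 1
            raise ValueError(
                f"{path}: u_true at data row {row} not in coding set {{{lo}, {hi}}}"
            )
        u_true = df["u_true"].to_numpy(dtype=float)
    extra = [c for c in df.columns if c not in (*REQUIRED_COLUMNS, "u_true")]
    covariates = df[extra].to_numpy(dtype=float) if extra else None
    return Cohort(
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
        arm=df["arm"].to_numpy(dtype=int),
        coding=coding,
        u_true=u_true,
        covariates=covariates,
    )


def write_cohort(cohort: Cohort, path: str | Path, include_u: bool = True) -> None:
    cohort.to_frame(include_u=include_u).to_csv(path, index=False)


def write_manifest(path: str | Path, config: dict[str, Any]) -> None:
    """Record the exact run configuration (seeds included) for reproducibility."""
    from . import __version__

    payload = {"rmstqba_version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def load_config(path: str | Path) -> dict[str, Any]:
    """Flat YAML/JSON config mirroring the CLI options; CLI flags override."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping of option names to values")
    return data
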