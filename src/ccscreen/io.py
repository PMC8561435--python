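"""Delimited-text I/O for case-cohort data, screening results and summaries.

Case-cohort files are tab- (or comma-) delimited with header columns
``subject_id, X, Delta, xi, Z1..Zp`` (or named covariates); masked
covariates are written as ``NA``.  A JSON sidecar (``<path>.json``)
records the sampling probability, seed and design parameters so a file
round-trips without loss.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CaseCohortData
from .evaluation import ReplicationSummary
from .screening import ScreeningResults

__all__ = [
    "write_case_cohort",
    "read_case_cohort",
    "write_screening_result",
    "read_screening_result",
    "write_summary",
    "write_manifest",
]

_META_COLS = ("subject_id", "X", "Delta", "xi")


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_case_cohort(
    data: CaseCohortData,
    path: str | Path,
    design=None,
    seed: int | None = None,
    sep: str = "\t",
) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": np.arange(1, data.n + 1),
            "X": data.X,
            "Delta": data.Delta,
            "xi": data.xi,
        }
    )
    for j in range(data.p):
        df[f"Z{j + 1}"] = data.Z_obs[:, j]
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.10g")
    meta: dict = {"pi": data.pi, "seed": seed}
    if design is not None:
        d = dataclasses.asdict(design)
        d["alpha"] = np.asarray(d["alpha"]).tolist()
        meta["design"] = d
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_case_cohort(path: str | Path) -> CaseCohortData:
    """Read and validate a case-cohort file; delimiter auto-detected.

    A case or subcohort member with missing covariates is a hard error
    (those rows must be fully observed under the design); a non-member
    with observed covariates only warns and the covariates are masked.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"])
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing columns {missing}")
    cov_cols = [c for c in df.columns if c not in _META_COLS]
    if not cov_cols:
        raise ValueError("no covariate columns found")
    X = df["X"].to_numpy(float)
    Delta = df["Delta"].to_numpy()
    xi = df["xi"].to_numpy()
    if not np.isin(Delta, (0, 1)).all():
        raise ValueError("Delta must be binary")
    if not np.isin(xi, (0, 1)).all():
        raise ValueError("xi must be binary")
    if np.any(X <= 0):
        raise ValueError("observed times must be positive")
    Z = df[cov_cols].to_numpy(float)
    member = (Delta.astype(int) == 1) | (xi.astype(int) == 1)
    row_has_na = np.isnan(Z).any(axis=1)
    bad = member & row_has_na
    if bad.any():
        rid = df.loc[np.flatnonzero(bad)[0], "subject_id"]
        raise ValueError(
            f"subject {rid} is a case or subcohort member but has NA covariates"
        )
    stray = ~member & ~np.isnan(Z).all(axis=1)
    if stray.any():
        warnings.warn(
            f"{int(stray.sum())} non-member rows had observed covariates; masking them",
            stacklevel=2,
        )
        Z[~member] = np.nan
    pi = None
    side = _sidecar(path)
    if side.exists():
        pi = json.loads(side.read_text()).get("pi")
    return CaseCohortData(X=X, Delta=Delta.astype(int), xi=xi.astype(int), Z_obs=Z, pi=pi)


def write_screening_result(result: ScreeningResults, path: str | Path, sep: str = "\t") -> None:
    result.to_frame().to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_screening_result(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def write_summary(summary: ReplicationSummary, path: str | Path, sep: str = "\t") -> None:
    """One design-cell row: method, median/IQR of S, Pe per active, Pa."""
    row: dict = {
        "method": summary.method,
        "S_median": summary.S_median,
        "S_iqr": summary.S_iqr,
    }
    for j, v in sorted(summary.Pe.items()):
        row[f"Pe_Z{j + 1}"] = "-" if not np.isfinite(v) else v
    row["Pa"] = summary.Pa
    pd.DataFrame([row]).to_csv(path, sep=sep, index=False, float_format="%.4g")


def write_manifest(config: dict, path: str | Path) -> None:
    """Machine-readable run manifest next to the outputs."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    Path(path).write_text(json.dumps(config, indent=2, default=_default))
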