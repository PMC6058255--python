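"""Dataset CSV format, run configuration, and result serialization.

The exchange format for time-course data is a plain UTF-8 CSV with header
``arm_id,baicalein_uM,analyte,time_h,replicate,value`` ("." decimal, full
float precision, so a write→read round trip is value-exact).  Configurations
and fit/recovery results travel as schema-validated JSON.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .datagen import DATASET_COLUMNS, ErrorModel, StudyDesign, default_design
from .model import ANALYTES
from .params import PDParameters, baicalein_reference_params


class DatasetError(ValueError):
    """Base class for dataset format violations."""


class MissingColumnsError(DatasetError):
    pass


class MalformedRowError(DatasetError):
    pass


class NegativeValueError(DatasetError):
    pass


class UnknownAnalyteError(DatasetError):
    pass


class DuplicateKeyError(DatasetError):
    pass


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a dataset CSV (canonical column order, full float precision)."""
    dataset[list(DATASET_COLUMNS)].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV.

    Raises a distinct :class:`DatasetError` subclass per violation, naming
    the offending CSV line numbers (header = line 1).  A header-only file
    yields an empty dataset with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise MissingColumnsError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        warnings.warn(f"{path}: header-only file, empty dataset", stacklevel=2)
        return df.assign(
            baicalein_uM=pd.Series(dtype=float),
            time_h=pd.Series(dtype=float),
            replicate=pd.Series(dtype=int),
            value=pd.Series(dtype=float),
        )[list(DATASET_COLUMNS)]

    lines = df.index.to_numpy() + 2  # CSV line numbers
    out = df.copy()
    for col in ("baicalein_uM", "time_h", "value"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            raise MalformedRowError(
                f"{path}: non-numeric {col!r} on lines {[int(x) for x in lines[bad]]}"
            )
        out[col] = converted.astype(float)
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    if rep.isna().any() or not np.allclose(rep.dropna() % 1, 0):
        bad = rep.isna() | (rep % 1 != 0)
        raise MalformedRowError(
            f"{path}: non-integer 'replicate' on lines {[int(x) for x in lines[bad]]}"
        )
    out["replicate"] = rep.astype(int)

    neg = out["value"] < 0
    if neg.any():
        raise NegativeValueError(
            f"{path}: negative value on lines {[int(x) for x in lines[neg]]}"
        )
    unknown = ~out["analyte"].isin(ANALYTES)
    if unknown.any():
        raise UnknownAnalyteError(
            f"{path}: unknown analyte on lines {[int(x) for x in lines[unknown]]} "
            f"(expected one of {ANALYTES})"
        )
    dup = out.duplicated(subset=["arm_id", "analyte", "time_h", "replicate"])
    if dup.any():
        raise DuplicateKeyError(
            f"{path}: duplicate (arm, analyte, time, replicate) on lines "
            f"{[int(x) for x in lines[dup]]}"
        )
    return out[list(DATASET_COLUMNS)]


class FitOptions(BaseModel):
    """Optimizer controls for a pooled-ML fit."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_starts: int = Field(default=8, ge=1)
    maxiter: int = Field(default=400, ge=1)
    error_model_kind: str = "proportional"


class RunConfig(BaseModel):
    """One self-contained run description; round-trips losslessly as JSON.

    Unknown keys are rejected, so a typo in a config file fails loudly
    instead of silently falling back to a default.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    params: PDParameters = Field(default_factory=baicalein_reference_params)
    fixed: tuple[str, ...] = (
        "k_out_inos",
        "k_out_no",
        "tnf0",
        "il6_0",
        "inos0",
        "no0",
    )
    bounds: dict[str, tuple[float, float]] | None = None
    design: StudyDesign = Field(default_factory=default_design)
    error_model: ErrorModel = ErrorModel(kind="proportional", sigma_prop=0.10)
    solver_rtol: float = Field(default=1e-8, gt=0)
    seed: int = 0
    fit_options: FitOptions = FitOptions()
    output_dir: str = "."

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON form, for run logging."""
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    return RunConfig(**json.loads(Path(path).read_text()))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))


def save_json(obj: dict, path) -> None:
    """Write a JSON result file (numpy scalars coerced to Python types)."""

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
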