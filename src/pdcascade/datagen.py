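"""Synthetic time-course data with the structure of the RAW264.7 experiment.

Generates long-format datasets of the four analytes (TNF-α, IL-6 by ELISA;
iNOS as a relative immunoblot ratio; NO/nitrite by Griess) across the four
LPS-stimulated treatment arms (0/10/20/40 μM baicalein) at the fitted
observation times, with a configurable residual-error model.  Datasets are
pandas DataFrames with columns ``arm_id, baicalein_uM, analyte, time_h,
replicate, value`` — the exact shape the estimator consumes.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import ANALYTES, predict_states, simulate_cascade
from .params import PDParameters

#: Required dataset columns, in canonical order.
DATASET_COLUMNS: tuple[str, ...] = (
    "arm_id",
    "baicalein_uM",
    "analyte",
    "time_h",
    "replicate",
    "value",
)


class TreatmentArm(BaseModel):
    """One LPS-stimulated arm with a fixed baicalein concentration (μM)."""

    model_config = ConfigDict(frozen=True)

    arm_id: str
    baicalein_conc: float = Field(ge=0.0)
    lps: bool = True


class StudyDesign(BaseModel):
    """Arms, observation times and replicate counts — the experiment blueprint."""

    model_config = ConfigDict(frozen=True)

    arms: tuple[TreatmentArm, ...]
    times: tuple[float, ...]
    replicates: dict[str, int]

    @model_validator(mode="after")
    def _check(self) -> "StudyDesign":
        t = np.asarray(self.times)
        if len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        for analyte, n in self.replicates.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")
            if n < 1:
                raise ValueError(f"replicate count for {analyte} must be >= 1")
        if set(self.replicates) != set(ANALYTES):
            raise ValueError("replicates must cover all four analytes")
        return self

    def n_records(self) -> int:
        return len(self.arms) * len(self.times) * sum(self.replicates.values())

    def concentrations(self) -> list[float]:
        return [a.baicalein_conc for a in self.arms]


class ErrorModel(BaseModel):
    """Residual-error model applied on the observation scale.

    ``additive``:      y = f + sigma_add * eps
    ``proportional``:  y = f * (1 + sigma_prop * eps)
    ``power``:         y = f + sigma_add * f**power_exponent * eps

    with eps ~ N(0, 1), truncated at 0 after noise is applied (negative
    concentrations are unphysical).  "Multiplicative" weighting is read as
    proportional, the standard convention behind population-PD software
    weighting options.
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["additive", "proportional", "power"] = "proportional"
    sigma_add: float = Field(default=0.0, ge=0.0)
    sigma_prop: float = Field(default=0.0, ge=0.0)
    power_exponent: float = 1.0

    def sigma_for(self, pred: np.ndarray) -> np.ndarray:
        """Residual standard deviation at each prediction."""
        pred = np.asarray(pred, dtype=float)
        if self.kind == "additive":
            return np.full_like(pred, self.sigma_add)
        if self.kind == "proportional":
            return self.sigma_prop * pred
        return self.sigma_add * pred**self.power_exponent


def default_design(include_24h: bool = False) -> StudyDesign:
    """The fitted study design: 4 arms × 5 times, n = 3 (n = 6 for iNOS).

    Times are hours post-LPS {1, 2, 4, 8, 12}; the 24 h point (where the
    treated and untreated trajectories have converged) is excluded from
    fitting by default and can be re-added with ``include_24h``.
    """
    times = (1.0, 2.0, 4.0, 8.0, 12.0) + ((24.0,) if include_24h else ())
    return StudyDesign(
        arms=tuple(
            TreatmentArm(arm_id=f"bai{int(c)}", baicalein_conc=float(c))
            for c in (0, 10, 20, 40)
        ),
        times=times,
        replicates={"TNF": 3, "IL6": 3, "NO": 3, "iNOS": 6},
    )


def predict_design(
    params: PDParameters,
    design: StudyDesign,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Noise-free expectation surface: one record per design cell × replicate."""
    params.check_arms(design.concentrations())
    times = np.asarray(design.times, dtype=float)
    frames = []
    for arm in design.arms:
        if params.k_out_inos == 0.0 and params.k_out_no == 0.0:
            states = predict_states(params, arm.baicalein_conc, times)
        else:
            grid = np.concatenate([[0.0], times])
            traj = simulate_cascade(params, arm.baicalein_conc, grid, rtol=rtol)
            states = {k: v[1:] for k, v in traj.states().items()}
        for analyte in ANALYTES:
            n_rep = design.replicates[analyte]
            frames.append(
                pd.DataFrame(
                    {
                        "arm_id": arm.arm_id,
                        "baicalein_uM": arm.baicalein_conc,
                        "analyte": analyte,
                        "time_h": np.repeat(times, n_rep),
                        "replicate": np.tile(np.arange(1, n_rep + 1), len(times)),
                        "value": np.repeat(states[analyte], n_rep),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[list(DATASET_COLUMNS)]


def apply_error(
    values, error_model: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Add residual noise to noise-free values; results truncated at 0."""
    values = np.asarray(values, dtype=float)
    eps = rng.standard_normal(values.shape)
    noisy = values + error_model.sigma_for(values) * eps
    return np.clip(noisy, 0.0, None)


def generate_dataset(
    params: PDParameters,
    design: StudyDesign,
    error_model: ErrorModel,
    seed: int,
) -> pd.DataFrame:
    """Simulate one full dataset; the seed fully determines the output.

    Generation metadata (parameters, error model, seed) is stored in
    ``DataFrame.attrs["meta"]``.
    """
    df = predict_design(params, design)
    rng = np.random.default_rng(seed)
    df = df.copy()
    df["value"] = apply_error(df["value"].to_numpy(), error_model, rng)
    df.attrs["meta"] = {
        "params": params.model_dump(),
        "error_model": error_model.model_dump(),
        "seed": int(seed),
        "design": design.model_dump(),
    }
    return df
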