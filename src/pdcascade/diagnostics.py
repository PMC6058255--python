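"""Goodness-of-fit and predictive-check surfaces for fitted cascade models.

Everything here is table-first: the GOF record table, the VPC envelope table
and the dense time-course table are plain DataFrames ready for CSV export;
matplotlib rendering is a thin optional layer on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datagen import ErrorModel, StudyDesign, generate_dataset, predict_design
from .estimate import FitResult, _Problem, design_from_dataset
from .model import ANALYTES, simulate_cascade
from .params import PDParameters


def gof(
    fit_result: FitResult,
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed-vs-predicted table plus per-analyte summary statistics.

    Returns ``(table, summary)``.  The table carries one row per record with
    observed, predicted, residual (observed - predicted) and the residual
    standardized by the fitted error model's standard deviation at that
    prediction.  The summary holds, per analyte, the slope of observed vs
    predicted through the origin (1 for a perfect fit), the intercept-free
    R², and the mean standardized residual (0 ± 3/√N for a well-specified
    fit).
    """
    design = design or design_from_dataset(dataset)
    prob = _Problem(dataset, design)
    pred = prob.predictions(fit_result.estimates)
    obs = prob.obs
    table = dataset.copy()
    table["predicted"] = pred
    table["residual"] = obs - pred
    zeta = {"additive": 0.0, "proportional": 1.0}.get(fit_result.error_kind, 0.5)
    sd = np.empty_like(pred)
    for a in ANALYTES:
        mask = table["analyte"].to_numpy() == a
        if not mask.any():
            continue
        sigma = fit_result.sigmas.get(a, np.nan)
        sd[mask] = sigma * np.where(zeta != 0, pred[mask] ** zeta, 1.0)
    table["standardized_residual"] = table["residual"] / sd

    rows = []
    for a in ANALYTES:
        sub = table[table["analyte"] == a]
        if sub.empty:
            continue
        o = sub["value"].to_numpy()
        p = sub["predicted"].to_numpy()
        slope = float(np.sum(o * p) / np.sum(p * p))
        rows.append(
            {
                "analyte": a,
                "n": len(sub),
                "slope_through_origin": slope,
                "mean_standardized_residual": float(
                    sub["standardized_residual"].mean()
                ),
                "rmse": float(np.sqrt(np.mean(sub["residual"] ** 2))),
            }
        )
    return table, pd.DataFrame(rows)


def vpc(
    params: PDParameters,
    error_model: ErrorModel,
    design: StudyDesign,
    n_sim: int = 200,
    quantiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    seed: int = 0,
    observed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predictive-check envelope per (arm, analyte, time).

    Simulates ``n_sim`` replicate datasets, reduces each design cell to its
    replicate median, and reports the requested percentiles of those medians
    across simulations alongside the noise-free prediction.  If ``observed``
    is given, its cell medians are attached for overlay.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    keys = ["arm_id", "analyte", "time_h"]
    noise_free = (
        predict_design(params, design).groupby(keys, sort=True)["value"].first()
    )
    medians = []
    for i in range(n_sim):
        ds = generate_dataset(params, design, error_model, seed=seed + i)
        medians.append(ds.groupby(keys, sort=True)["value"].median())
    stack = np.vstack([m.to_numpy() for m in medians])
    out = noise_free.rename("prediction").reset_index()
    for q in quantiles:
        out[f"q{q:g}"] = np.percentile(stack, q, axis=0)
    if observed is not None:
        obs_med = observed.groupby(keys, sort=True)["value"].median()
        out = out.merge(
            obs_med.rename("observed_median").reset_index(), on=keys, how="left"
        )
    return out


def timecourse_plot_data(
    params: PDParameters,
    arms,
    grid,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Dense per-arm trajectories in tidy form, for Figure-style overlays.

    ``arms`` is a list of concentrations (μM) or objects with a
    ``baicalein_conc`` attribute; values match :func:`simulate_cascade`
    bit-exactly.
    """
    frames = []
    for arm in arms:
        conc = getattr(arm, "baicalein_conc", arm)
        arm_id = getattr(arm, "arm_id", f"bai{conc:g}")
        traj = simulate_cascade(params, float(conc), np.asarray(grid, float), rtol=rtol)
        for analyte, series in traj.states().items():
            frames.append(
                pd.DataFrame(
                    {
                        "arm_id": arm_id,
                        "baicalein_uM": float(conc),
                        "analyte": analyte,
                        "time_h": traj.t,
                        "value": series,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def plot_gof(table: pd.DataFrame, path=None):
    """Observed-vs-predicted panels with the x = y diagonal, one per analyte."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = [a for a in ANALYTES if (table["analyte"] == a).any()]
    fig, axes = plt.subplots(1, len(analytes), figsize=(4 * len(analytes), 4))
    for ax, a in zip(np.atleast_1d(axes), analytes):
        sub = table[table["analyte"] == a]
        ax.scatter(sub["predicted"], sub["value"], s=12, alpha=0.6)
        lim = [0, max(sub["predicted"].max(), sub["value"].max()) * 1.05]
        ax.plot(lim, lim, color="palevioletred", lw=1)
        ax.set_xlabel("predicted")
        ax.set_ylabel("observed")
        ax.set_title(a)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_timecourse(curves: pd.DataFrame, observed: pd.DataFrame | None = None, path=None):
    """Model curves per analyte, one line per arm, with optional data overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    analytes = [a for a in ANALYTES if (curves["analyte"] == a).any()]
    fig, axes = plt.subplots(1, len(analytes), figsize=(4 * len(analytes), 4))
    for ax, a in zip(np.atleast_1d(axes), analytes):
        for arm_id, sub in curves[curves["analyte"] == a].groupby("arm_id"):
            ax.plot(sub["time_h"], sub["value"], label=str(arm_id))
        if observed is not None:
            obs = observed[observed["analyte"] == a]
            ax.scatter(obs["time_h"], obs["value"], s=10, color="k", alpha=0.5)
        ax.set_xlabel("time post-LPS (h)")
        ax.set_ylabel(a)
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
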