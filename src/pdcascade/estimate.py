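"""Pooled maximum-likelihood estimation of the turnover cascade.

All observations across arms, analytes, times and replicates are treated as
one population-level dataset with a Gaussian residual-error model (naive
pooling); there are no random effects.  Per-analyte residual standard
deviations are profiled out of the likelihood analytically, so the optimizer
works only on the structural parameters.  Rates, baselines and the NO
exponent are optimized on the log scale; the inhibition coefficient and the
two lag times on the natural scale, with bounds keeping the inhibition
fraction below 1 at the largest arm concentration.

The public surface is the scikit-learn style :class:`CascadeRegressor`; the
module-level :func:`fit` and :func:`recover` are thin wrappers over it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.tools.numdiff import approx_hess

from .datagen import (
    DATASET_COLUMNS,
    ErrorModel,
    StudyDesign,
    TreatmentArm,
    generate_dataset,
)
from .model import ANALYTES, predict_states, simulate_cascade
from .params import PARAM_NAMES, PDParameters

logger = logging.getLogger(__name__)

#: Parameters optimized on the log scale (strictly positive quantities).
LOG_SCALE_PARAMS = frozenset(
    {
        "k_in_tnf",
        "k_out_tnf",
        "k_in_il6",
        "k_out_il6",
        "k_in_inos",
        "k_out_inos",
        "k_in_no",
        "k_out_no",
        "delta",
        "tnf0",
        "il6_0",
        "inos0",
        "no0",
    }
)

#: Default fixed set: zero elimination of iNOS/NO plus all baselines
#: (baselines are the time-0 control values, not free parameters).
DEFAULT_FIXED = frozenset(
    {"k_out_inos", "k_out_no", "tnf0", "il6_0", "inos0", "no0"}
)

_POWER_EXPONENT = {"additive": 0.0, "proportional": 1.0}


def information_criteria(minus2ll: float, p: int, n_obs: int) -> tuple[float, float]:
    """AIC = -2LL + 2p and BIC = -2LL + p·ln(n_obs)."""
    if p < 1 or n_obs < 1:
        raise ValueError("p and n_obs must be >= 1")
    return minus2ll + 2.0 * p, minus2ll + p * math.log(n_obs)


def design_from_dataset(df: pd.DataFrame) -> StudyDesign:
    """Reconstruct the study design implied by a long-format dataset."""
    arms = tuple(
        TreatmentArm(arm_id=str(arm_id), baicalein_conc=float(conc))
        for (arm_id, conc), _ in df.groupby(["arm_id", "baicalein_uM"], sort=True)
    )
    times = tuple(sorted(df["time_h"].unique()))
    reps = {
        a: int(df[df["analyte"] == a].groupby(["arm_id", "time_h"]).size().max())
        for a in ANALYTES
        if (df["analyte"] == a).any()
    }
    for a in ANALYTES:
        reps.setdefault(a, 1)
    return StudyDesign(arms=arms, times=times, replicates=reps)


@dataclass
class FitResult:
    """Outcome of one pooled-ML fit."""

    estimates: PDParameters
    fixed: frozenset[str]
    error_kind: str
    sigmas: dict[str, float]
    minus2ll: float
    aic: float
    bic: float
    n_obs: int
    n_free_structural: int
    n_error_params: int
    converged: bool
    n_starts: int
    n_converged: int
    best_start: int
    n_best_reproduced: int
    iterations: int
    cv_percent: dict[str, float] | None = None
    free_names: tuple[str, ...] = ()

    @property
    def p(self) -> int:
        return self.n_free_structural + self.n_error_params

    def to_dict(self) -> dict:
        d = {
            "estimates": self.estimates.model_dump(),
            "fixed": sorted(self.fixed),
            "error_kind": self.error_kind,
            "sigmas": self.sigmas,
            "minus2ll": self.minus2ll,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_free_structural": self.n_free_structural,
            "n_error_params": self.n_error_params,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "best_start": self.best_start,
            "n_best_reproduced": self.n_best_reproduced,
            "iterations": self.iterations,
            "cv_percent": self.cv_percent,
            "free_names": list(self.free_names),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["estimates"] = PDParameters(**d["estimates"])
        d["fixed"] = frozenset(d["fixed"])
        d["free_names"] = tuple(d["free_names"])
        if d.get("cv_percent") is not None:
            d["cv_percent"] = {k: float(v) for k, v in d["cv_percent"].items()}
        return cls(**d)


class _Problem:
    """Dataset indexing + prediction plumbing shared by NLL and fitting."""

    def __init__(self, df: pd.DataFrame, design: StudyDesign):
        missing = set(DATASET_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        bad = set(df["analyte"].unique()) - set(ANALYTES)
        if bad:
            raise ValueError(f"unknown analytes in dataset: {sorted(bad)}")
        self.design = design
        self.times = np.asarray(design.times, dtype=float)
        self.concs = np.asarray(design.concentrations(), dtype=float)
        arm_ids = [a.arm_id for a in design.arms]
        arm_code = df["arm_id"].map({aid: i for i, aid in enumerate(arm_ids)})
        if arm_code.isna().any():
            raise ValueError("dataset contains arms not present in the design")
        self.arm_code = arm_code.to_numpy(dtype=int)
        self.analyte_code = (
            df["analyte"].map({a: i for i, a in enumerate(ANALYTES)}).to_numpy(int)
        )
        t_idx = np.searchsorted(self.times, df["time_h"].to_numpy(float))
        t_idx = np.clip(t_idx, 0, len(self.times) - 1)
        if not np.allclose(self.times[t_idx], df["time_h"].to_numpy(float)):
            raise ValueError("dataset contains times not present in the design")
        self.time_code = t_idx
        self.obs = df["value"].to_numpy(dtype=float)
        self.n_obs = len(df)
        # per-analyte record masks for sigma profiling
        self.analyte_masks = [self.analyte_code == i for i in range(len(ANALYTES))]

    def predict_matrix(self, params: PDParameters) -> np.ndarray:
        """Predicted states, shape (n_arms, n_analytes, n_times)."""
        out = np.empty((len(self.concs), len(ANALYTES), len(self.times)))
        for i, conc in enumerate(self.concs):
            if params.k_out_inos == 0.0 and params.k_out_no == 0.0:
                states = predict_states(params, conc, self.times)
            else:
                grid = np.concatenate([[0.0], self.times])
                traj = simulate_cascade(params, conc, grid)
                states = {k: v[1:] for k, v in traj.states().items()}
            for j, a in enumerate(ANALYTES):
                out[i, j] = states[a]
        return out

    def predictions(self, params: PDParameters) -> np.ndarray:
        mat = self.predict_matrix(params)
        return mat[self.arm_code, self.analyte_code, self.time_code]

    def profiled_minus2ll(
        self, params: PDParameters, zeta: float, analytes=None
    ) -> tuple[float, dict[str, float]]:
        """-2LL with per-analyte sigma at its closed-form MLE.

        zeta is the power exponent of the variance weight (0 additive,
        1 proportional); sigma_a^2 = mean_a[(obs - pred)^2 / pred^(2 zeta)].
        ``analytes`` restricts the sum to a subset (used by the staged
        warm start).
        """
        pred = self.predictions(params)
        if np.any(~np.isfinite(pred)) or (zeta > 0 and np.any(pred <= 0)):
            return np.inf, {}
        res = self.obs - pred
        m2ll = 0.0
        sigmas: dict[str, float] = {}
        for j, a in enumerate(ANALYTES):
            if analytes is not None and a not in analytes:
                continue
            mask = self.analyte_masks[j]
            n_a = int(mask.sum())
            if n_a == 0:
                continue
            w = pred[mask] ** zeta if zeta != 0 else np.ones(n_a)
            s2 = float(np.mean((res[mask] / w) ** 2))
            # floor keeps an exact (noise-free) fit from degenerating to
            # -inf; 1e-12 on the weighted scale (residual CV 1e-6) is far
            # below assay noise and keeps the surface flat at an exact fit
            floor = 1e-12 * (float(np.mean((self.obs[mask] / w) ** 2)) + 1e-300)
            s2 = max(s2, floor)
            m2ll += n_a * (math.log(2.0 * math.pi * s2) + 1.0)
            if zeta != 0:
                m2ll += 2.0 * float(np.sum(np.log(w)))
            sigmas[a] = math.sqrt(s2)
        return m2ll, sigmas


def neg_log_likelihood(
    params: PDParameters,
    error_model: ErrorModel | dict[str, ErrorModel],
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
) -> float:
    """Pooled Gaussian negative log-likelihood at explicit error sigmas.

    ``error_model`` is a single :class:`ErrorModel` applied to every analyte,
    or a mapping analyte → ErrorModel.  Returns +inf (with a log message) for
    parameter sets violating model invariants so optimizers can continue.
    """
    design = design or design_from_dataset(dataset)
    try:
        prob = _Problem(dataset, design)
        params.check_arms(design.concentrations())
        pred = prob.predictions(params)
    except (ValueError, RuntimeError) as exc:
        logger.info("NLL -> inf: %s", exc)
        return np.inf
    nll = 0.0
    for j, a in enumerate(ANALYTES):
        mask = prob.analyte_masks[j]
        if not mask.any():
            continue
        em = error_model[a] if isinstance(error_model, dict) else error_model
        sd = em.sigma_for(pred[mask])
        if np.any(sd <= 0):
            return np.inf
        res = prob.obs[mask] - pred[mask]
        nll += float(
            np.sum(0.5 * np.log(2.0 * np.pi * sd**2) + 0.5 * (res / sd) ** 2)
        )
    return nll


# ---------------------------------------------------------------------------
# Parameter transform
# ---------------------------------------------------------------------------


class _Transform:
    """Map free parameters between natural and optimization scale."""

    def __init__(
        self,
        init: PDParameters,
        fixed: frozenset[str],
        bounds: dict[str, tuple[float, float]] | None,
        max_conc: float,
    ):
        self.fixed = fixed
        self.free_names = tuple(n for n in PARAM_NAMES if n not in fixed)
        self.init = init
        bounds = dict(bounds or {})
        # alpha bound keeps f(C) < 1 at the largest arm concentration
        alpha_hi = 0.26 if max_conc <= 1 else min(0.26, 0.995 / math.log(max_conc))
        defaults: dict[str, tuple[float, float]] = {
            "alpha": (0.0, alpha_hi),
            "tau1": (0.0, 6.0),
            "tau2": (0.0, 6.0),
            "delta": (0.05, 5.0),
        }
        self.bounds_nat: dict[str, tuple[float, float]] = {}
        for name in self.free_names:
            if name in bounds:
                lo, hi = bounds[name]
            elif name in defaults:
                lo, hi = defaults[name]
            else:
                v = getattr(init, name)
                if v <= 0:
                    raise ValueError(
                        f"free log-scale parameter {name!r} needs a positive init"
                    )
                lo, hi = v / 1e3, v * 1e3
            if name in LOG_SCALE_PARAMS and lo <= 0:
                lo = max(lo, 1e-12)
            self.bounds_nat[name] = (lo, hi)

    def to_opt(self, params: PDParameters) -> np.ndarray:
        x = []
        for name in self.free_names:
            v = getattr(params, name)
            lo, hi = self.bounds_nat[name]
            v = min(max(v, lo), hi)
            x.append(math.log(v) if name in LOG_SCALE_PARAMS else v)
        return np.array(x)

    def to_params(self, x: np.ndarray) -> PDParameters:
        updates = {}
        for name, xi in zip(self.free_names, x):
            updates[name] = math.exp(xi) if name in LOG_SCALE_PARAMS else float(xi)
        return self.init.replace(**updates)

    def opt_bounds(self) -> list[tuple[float, float]]:
        out = []
        for name in self.free_names:
            lo, hi = self.bounds_nat[name]
            if name in LOG_SCALE_PARAMS:
                out.append((math.log(lo), math.log(hi)))
            else:
                out.append((lo, hi))
        return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

#: Stage order of the cascade: each analyte identifies its own parameters.
_STAGES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("TNF", ("alpha", "k_in_tnf", "k_out_tnf", "tnf0")),
    ("IL6", ("k_in_il6", "k_out_il6", "tau1", "il6_0")),
    ("iNOS", ("k_in_inos", "k_out_inos", "tau2", "inos0")),
    ("NO", ("k_in_no", "k_out_no", "delta", "no0")),
)


def _staged_warm_start(
    prob: _Problem,
    init: PDParameters,
    fixed: frozenset[str],
    bounds,
    zeta: float,
    max_conc: float,
    maxiter: int,
) -> PDParameters:
    """Sequential per-analyte pre-fit exploiting the feed-forward cascade.

    TNF-α is autonomous, so its parameters are identified from TNF-α records
    alone; each downstream analyte then identifies its own turnover
    parameters given the upstream estimates.  The result seeds the joint
    optimization, which removes most of the joint surface's local minima.
    """
    lag_grid = (0.25, 1.0, 1.75, 2.5, 3.5, 5.0)
    current = init
    for analyte, stage_names in _STAGES:
        free_stage = [n for n in stage_names if n not in fixed]
        if not free_stage or not prob.analyte_masks[ANALYTES.index(analyte)].any():
            continue
        stage_fixed = frozenset(set(PARAM_NAMES) - set(free_stage))
        tr = _Transform(current, stage_fixed, bounds, max_conc)

        def objective(x: np.ndarray) -> float:
            try:
                params = tr.to_params(x)
                params.check_arms(prob.concs)
                m2ll, _ = prob.profiled_minus2ll(params, zeta, analytes={analyte})
            except (ValueError, RuntimeError):
                return 1e12
            return 0.5 * m2ll if np.isfinite(m2ll) else 1e12

        # lag likelihoods are multimodal with few observation times, so each
        # free lag is additionally started from a deterministic coarse grid
        starts = [current]
        lag_name = next((n for n in free_stage if n.startswith("tau")), None)
        if lag_name is not None:
            starts += [current.replace(**{lag_name: v}) for v in lag_grid]
        best_x, best_fun = None, np.inf
        for start in starts:
            res = minimize(
                objective,
                tr.to_opt(start),
                method="L-BFGS-B",
                bounds=tr.opt_bounds(),
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
            )
            if np.isfinite(res.fun) and res.fun < best_fun:
                best_x, best_fun = res.x, res.fun
        if best_x is not None and best_fun < 1e11:
            current = tr.to_params(best_x)
    return current


def fit(
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
    init: PDParameters | None = None,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    bounds: dict[str, tuple[float, float]] | None = None,
    error_model_kind: str = "proportional",
    n_starts: int = 8,
    seed: int = 0,
    maxiter: int = 400,
    reproduce_tol: float = 1e-2,
    power_exponent: float = 0.5,
    staged: bool = True,
) -> FitResult:
    """Fit the cascade to a dataset by pooled maximum likelihood.

    A staged warm start first identifies each analyte's parameters on its
    own records in cascade order (disable with ``staged=False``).  Bounded
    L-BFGS-B with ``n_starts`` multi-starts then polishes jointly: start 0
    is the staged point, start 1 is ``init`` itself, the rest jitter every
    free parameter by a log-uniform factor in [0.5, 2] (seeded).  Per-analyte
    residual sigmas are profiled analytically.  Raises if no start converges;
    warns if fewer than two starts reproduce the best -2LL within
    ``reproduce_tol``.
    """
    if init is None:
        raise ValueError("an initial parameter set is required")
    fixed = frozenset(fixed)
    design = design or design_from_dataset(dataset)
    prob = _Problem(dataset, design)
    zeta = _POWER_EXPONENT.get(error_model_kind, power_exponent)
    if error_model_kind not in ("additive", "proportional", "power"):
        raise ValueError(f"unknown error model kind {error_model_kind!r}")
    tr = _Transform(init, fixed, bounds, max(design.concentrations(), default=0.0))

    def objective(x: np.ndarray) -> float:
        try:
            params = tr.to_params(x)
            params.check_arms(prob.concs)
            m2ll, _ = prob.profiled_minus2ll(params, zeta)
        except (ValueError, RuntimeError):
            return 1e12
        return 0.5 * m2ll if np.isfinite(m2ll) else 1e12

    rng = np.random.default_rng(seed)
    max_conc = max(design.concentrations(), default=0.0)
    if staged:
        warm = _staged_warm_start(prob, init, fixed, bounds, zeta, max_conc, maxiter)
    else:
        warm = init
    x_init = tr.to_opt(warm)
    x_raw = tr.to_opt(init)
    opt_bounds = tr.opt_bounds()
    lo = np.array([b[0] for b in opt_bounds])
    hi = np.array([b[1] for b in opt_bounds])

    results = []
    for start in range(n_starts):
        if start == 0:
            x0 = x_init.copy()
        elif start == 1 and staged:
            x0 = x_raw.copy()
        else:
            factor = rng.uniform(math.log(0.5), math.log(2.0), size=len(x_init))
            x0 = np.empty_like(x_init)
            for i, name in enumerate(tr.free_names):
                if name in LOG_SCALE_PARAMS:
                    x0[i] = x_init[i] + factor[i]
                else:
                    x0[i] = x_init[i] * math.exp(factor[i])
            x0 = np.clip(x0, lo, hi)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=opt_bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        results.append((start, res))

    converged = [(s, r) for s, r in results if r.success and r.fun < 1e11]
    if not converged:
        raise RuntimeError(
            "no multi-start converged; messages: "
            + "; ".join(r.message for _, r in results)
        )
    best_start, best = min(converged, key=lambda sr: sr[1].fun)
    n_repro = sum(1 for _, r in converged if r.fun - best.fun <= reproduce_tol)
    if n_repro < 2 and n_starts > 1:
        logger.warning(
            "best -2LL reproduced by only %d/%d converged starts", n_repro, len(converged)
        )

    estimates = tr.to_params(best.x)
    m2ll, sigmas = prob.profiled_minus2ll(estimates, zeta)
    n_err = len(sigmas)
    p = len(tr.free_names) + n_err
    aic, bic = information_criteria(m2ll, p, prob.n_obs)
    return FitResult(
        estimates=estimates,
        fixed=fixed,
        error_kind=error_model_kind,
        sigmas=sigmas,
        minus2ll=m2ll,
        aic=aic,
        bic=bic,
        n_obs=prob.n_obs,
        n_free_structural=len(tr.free_names),
        n_error_params=n_err,
        converged=True,
        n_starts=n_starts,
        n_converged=len(converged),
        best_start=best_start,
        n_best_reproduced=n_repro,
        iterations=int(best.nit),
        free_names=tr.free_names,
    )


def parameter_cv(
    fit_result: FitResult,
    dataset: pd.DataFrame,
    design: StudyDesign | None = None,
    method: str = "hessian",
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """CV% = 100·SE/estimate for each free structural parameter.

    ``hessian`` inverts the numerical observed information of the profiled
    -2LL at the optimum; ``bootstrap`` resamples records with replacement
    within each (arm, analyte, time) cell and refits (single start from the
    estimates).
    """
    design = design or design_from_dataset(dataset)
    free = [n for n in fit_result.free_names]
    est = fit_result.estimates
    if method == "hessian":
        prob = _Problem(dataset, design)
        zeta = _POWER_EXPONENT.get(fit_result.error_kind, 0.5)
        theta0 = np.array([getattr(est, n) for n in free])
        scale = np.where(np.abs(theta0) > 0, np.abs(theta0), 1.0)

        def nll_nat(theta: np.ndarray) -> float:
            params = est.replace(**dict(zip(free, theta * scale)))
            m2ll, _ = prob.profiled_minus2ll(params, zeta)
            return 0.5 * m2ll if np.isfinite(m2ll) else 1e12

        hess = approx_hess(theta0 / scale, nll_nat)
        eigvals, eigvecs = np.linalg.eigh(hess)
        if np.min(eigvals) <= 1e-10 * np.max(np.abs(eigvals)):
            null_dims = [
                free[int(np.argmax(np.abs(eigvecs[:, i])))]
                for i in np.where(eigvals <= 1e-10 * np.max(np.abs(eigvals)))[0]
            ]
            raise np.linalg.LinAlgError(
                f"information matrix singular along {null_dims}"
            )
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov)) * scale
        return {
            n: float(100.0 * s / abs(t)) if t != 0 else float("inf")
            for n, s, t in zip(free, se, theta0)
        }
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        draws: list[dict[str, float]] = []
        groups = dataset.groupby(["arm_id", "analyte", "time_h"], sort=False)
        for _ in range(n_boot):
            parts = [
                g.iloc[rng.integers(0, len(g), size=len(g))] for _, g in groups
            ]
            boot = pd.concat(parts, ignore_index=True)
            try:
                fr = fit(
                    boot,
                    design,
                    init=est,
                    fixed=fit_result.fixed,
                    error_model_kind=fit_result.error_kind,
                    n_starts=1,
                    seed=int(rng.integers(2**31)),
                )
                draws.append({n: getattr(fr.estimates, n) for n in free})
            except RuntimeError:
                continue
        if len(draws) < max(10, n_boot // 4):
            raise RuntimeError(f"bootstrap: only {len(draws)}/{n_boot} fits converged")
        arr = pd.DataFrame(draws)
        return {
            n: float(100.0 * arr[n].std(ddof=1) / abs(getattr(est, n)))
            for n in free
        }
    raise ValueError(f"unknown CV method {method!r}")


# ---------------------------------------------------------------------------
# Simulation-refit recovery study
# ---------------------------------------------------------------------------


@dataclass
class RecoverySummary:
    """Aggregate of a simulation–refit parameter-recovery study."""

    true_params: PDParameters
    free_names: tuple[str, ...]
    medians: dict[str, float]
    relative_bias: dict[str, float]
    rmse: dict[str, float]
    coverage: dict[str, float] | None
    n_sim: int
    n_converged: int
    seeds: tuple[int, ...]
    estimates: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.free_names:
            rows.append(
                {
                    "parameter": n,
                    "truth": getattr(self.true_params, n),
                    "median": self.medians[n],
                    "relative_bias": self.relative_bias[n],
                    "rmse": self.rmse[n],
                    "coverage95": None if self.coverage is None else self.coverage[n],
                }
            )
        return pd.DataFrame(rows)


def recover(
    true_params: PDParameters,
    design: StudyDesign,
    error_model: ErrorModel,
    n_sim: int,
    seed: int,
    fixed: frozenset[str] | set[str] = DEFAULT_FIXED,
    n_starts: int = 4,
    compute_coverage: bool = True,
) -> RecoverySummary:
    """Simulate ``n_sim`` datasets from the truth and refit each one.

    Dataset i uses seed ``seed + i`` (i = 1..n_sim).  Each fit starts from
    the true values (start 0) plus log-uniform ×[0.5, 2] jittered starts.
    Medians, relative bias and RMSE are computed over converged fits only;
    raises if more than half fail.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    fixed = frozenset(fixed)
    free = tuple(n for n in PARAM_NAMES if n not in fixed)
    seeds = tuple(seed + i for i in range(1, n_sim + 1))
    rows, cover_rows = [], []
    n_fail = 0
    for ds_seed in seeds:
        ds = generate_dataset(true_params, design, error_model, seed=ds_seed)
        try:
            fr = fit(
                ds,
                design,
                init=true_params,
                fixed=fixed,
                error_model_kind=error_model.kind,
                n_starts=n_starts,
                seed=ds_seed,
                power_exponent=error_model.power_exponent,
            )
        except RuntimeError as exc:
            logger.warning("recovery fit (seed %d) failed: %s", ds_seed, exc)
            n_fail += 1
            continue
        rows.append({n: getattr(fr.estimates, n) for n in free} | {"seed": ds_seed})
        if compute_coverage:
            try:
                cv = parameter_cv(fr, ds, design, method="hessian")
                cover_rows.append(
                    {
                        n: abs(getattr(fr.estimates, n) - getattr(true_params, n))
                        <= 1.96 * abs(getattr(fr.estimates, n)) * cv[n] / 100.0
                        for n in free
                    }
                )
            except np.linalg.LinAlgError:
                cover_rows.append({n: np.nan for n in free})
    if n_fail > n_sim / 2:
        raise RuntimeError(f"{n_fail}/{n_sim} recovery fits failed to converge")
    est = pd.DataFrame(rows)
    medians = {n: float(est[n].median()) for n in free}
    rel_bias = {
        n: float((medians[n] - getattr(true_params, n)) / getattr(true_params, n))
        if getattr(true_params, n) != 0
        else float("nan")
        for n in free
    }
    rmse = {
        n: float(np.sqrt(np.mean((est[n] - getattr(true_params, n)) ** 2)))
        for n in free
    }
    coverage = None
    if compute_coverage and cover_rows:
        cdf = pd.DataFrame(cover_rows)
        coverage = {n: float(np.nanmean(cdf[n].astype(float))) for n in free}
    return RecoverySummary(
        true_params=true_params,
        free_names=free,
        medians=medians,
        relative_bias=rel_bias,
        rmse=rmse,
        coverage=coverage,
        n_sim=n_sim,
        n_converged=len(rows),
        seeds=seeds,
        estimates=est,
    )


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------


class CascadeRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for the LPS-driven cytokine cascade.

    ``fit`` consumes a long-format dataset (DataFrame with columns
    ``arm_id, baicalein_uM, analyte, time_h, replicate, value``); the study
    design is reconstructed from the data.  ``predict`` returns the model
    prediction for each record of a same-shaped frame.

    Parameters
    ----------
    init_params : PDParameters or dict, optional
        Structural starting values (defaults to the published baicalein
        reference estimates).
    fixed : collection of str
        Parameters held at their init values during fitting.
    error_model : {"additive", "proportional", "power"}
        Residual-error model; per-analyte sigmas are profiled.
    n_starts, seed, maxiter
        Multi-start optimizer controls.

    Attributes
    ----------
    params_ : PDParameters
        Maximum-likelihood structural estimates.
    sigmas_ : dict
        Per-analyte residual sigma estimates.
    result_ : FitResult
        Full fit record (-2LL, AIC, BIC, convergence metadata).
    """

    def __init__(
        self,
        init_params=None,
        fixed=DEFAULT_FIXED,
        error_model: str = "proportional",
        bounds=None,
        n_starts: int = 8,
        seed: int = 0,
        maxiter: int = 400,
    ):
        self.init_params = init_params
        self.fixed = fixed
        self.error_model = error_model
        self.bounds = bounds
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter

    def _init(self) -> PDParameters:
        from .params import baicalein_reference_params

        if self.init_params is None:
            return baicalein_reference_params()
        if isinstance(self.init_params, PDParameters):
            return self.init_params
        return PDParameters(**self.init_params)

    def fit(self, X: pd.DataFrame, y=None) -> "CascadeRegressor":
        design = design_from_dataset(X)
        self.result_ = fit(
            X,
            design,
            init=self._init(),
            fixed=self.fixed,
            bounds=self.bounds,
            error_model_kind=self.error_model,
            n_starts=self.n_starts,
            seed=self.seed,
            maxiter=self.maxiter,
        )
        self.params_ = self.result_.estimates
        self.sigmas_ = self.result_.sigmas
        self.minus2ll_ = self.result_.minus2ll
        self.aic_ = self.result_.aic
        self.bic_ = self.result_.bic
        self.design_ = design
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        prob = _Problem(X, design_from_dataset(X))
        return prob.predictions(self.params_)

    def score(self, X: pd.DataFrame, y=None) -> float:
        """Mean log-likelihood per record at the fitted parameters."""
        em = {
            a: ErrorModel(kind="proportional", sigma_prop=s)
            if self.error_model == "proportional"
            else ErrorModel(kind="additive", sigma_add=s)
            for a, s in self.sigmas_.items()
        }
        return -neg_log_likelihood(self.params_, em, X) / len(X)
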