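"""Turnover cascade LPS → TNF-α → {IL-6, iNOS → NO} with log-linear inhibition.

The model is a chain of indirect-response (turnover) equations:

    dTNF/dt  = k_in_tnf * (1 - f(C)) - k_out_tnf * TNF,   f(C) = alpha * ln(C)
    dIL6/dt  = k_in_il6 * TNF(t - tau1) - k_out_il6 * IL6
    diNOS/dt = k_in_inos * TNF(t - tau2) - k_out_inos * iNOS
    dNO/dt   = k_in_no * iNOS**delta - k_out_no * NO

with TNF(t) ≡ tnf0 for t ≤ 0 (pre-stimulus history).  Time zero is the moment
of LPS addition; baicalein is pre-incubated, so its effect enters as the
constant fraction f(C) from t = 0.  TNF-α is autonomous and linear, so it has
a closed-form solution that doubles as the oracle for the numerical solver
and as the exact delayed-input lookup.

Two solution routes are provided:

* :func:`simulate_cascade` — general numerical integration (any k_out).
* :func:`predict_states` — semi-analytic evaluation for the conventional
  configuration k_out_inos = k_out_no = 0 (IL-6 has a piecewise closed form;
  iNOS is a closed-form integral of delayed TNF-α; NO needs one smooth
  quadrature).  This is the fast path used inside likelihood evaluation and
  agrees with the ODE solver to solver tolerance (unit-tested).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator

from .params import PDParameters

logger = logging.getLogger(__name__)

#: Analyte labels in canonical order.
ANALYTES: tuple[str, ...] = ("TNF", "IL6", "iNOS", "NO")

_GL_NODES, _GL_WEIGHTS = leggauss(48)


def drug_effect(alpha: float, conc: float) -> float:
    """Inhibition fraction of TNF-α production, f(C) = alpha * ln(C).

    Defined as 0 for C ≤ 1 μM (the control arm has no drug and ln C ≤ 0
    would otherwise predict stimulation); raises if the fraction reaches 1,
    which would mean total shutdown of production — outside the log-linear
    model's validity.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if conc <= 1.0:
        return 0.0
    f = alpha * math.log(conc)
    if f >= 1.0:
        raise ValueError(
            f"alpha*ln(C) = {f:.4g} >= 1 at C = {conc} μM: "
            "the model predicts negative production"
        )
    return f


def tnf_closed_form(params: PDParameters, conc: float, t):
    """Exact TNF-α trajectory (vectorized over ``t``).

    For k_out > 0:  S/k_out + (tnf0 - S/k_out) * exp(-k_out * t)
    For k_out = 0:  tnf0 + S * t,  with S = k_in_tnf * (1 - f(C)).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    s = params.k_in_tnf * (1.0 - drug_effect(params.alpha, conc))
    k = params.k_out_tnf
    if k > 0:
        a = s / k
        return a + (params.tnf0 - a) * np.exp(-k * t)
    return params.tnf0 + s * t


def tnf_delayed(params: PDParameters, conc: float, t, tau: float):
    """TNF-α at time t - tau, using the constant pre-stimulus history tnf0."""
    t = np.asarray(t, dtype=float)
    shifted = np.maximum(t - tau, 0.0)
    out = tnf_closed_form(params, conc, shifted)
    return np.where(t - tau > 0, out, params.tnf0)


def inos_relative_ratio(
    inos_signal: float, gapdh_signal: float, inos0_signal: float, gapdh0_signal: float
) -> float:
    """Relative iNOS expression: (iNOS/GAPDH) / (iNOS₀/GAPDH₀).

    The immunoblot band intensity of iNOS is normalized to the GAPDH loading
    control, then to the same quantity at time 0, giving a dimensionless
    expression level that equals 1 at baseline by construction.
    """
    signals = (inos_signal, gapdh_signal, inos0_signal, gapdh0_signal)
    if any(s <= 0 for s in signals):
        raise ValueError(f"all band intensities must be > 0, got {signals}")
    return (inos_signal / gapdh_signal) / (inos0_signal / gapdh0_signal)


@dataclass(frozen=True)
class Trajectory:
    """Dense noise-free solution of the four states for one treatment arm."""

    conc: float
    t: np.ndarray
    tnf: np.ndarray
    il6: np.ndarray
    inos: np.ndarray
    no: np.ndarray
    interpolation: str = "pchip"
    _tnf_interp: PchipInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def states(self) -> dict[str, np.ndarray]:
        return {"TNF": self.tnf, "IL6": self.il6, "iNOS": self.inos, "NO": self.no}

    def tnf_at(self, t: float) -> float:
        """Monotone-cubic interpolated TNF-α at an off-grid time."""
        interp = self._tnf_interp or PchipInterpolator(self.t, self.tnf)
        return float(interp(t))


def delayed_input(
    trajectory: Trajectory, t: float, tau: float, history_value: float
) -> float:
    """Delayed TNF-α lookup TNF(t - tau) against a stored trajectory.

    Returns ``history_value`` (the pre-stimulus baseline) when t - tau ≤ 0,
    otherwise the monotone-cubic interpolated trajectory value.  Extrapolation
    beyond the stored grid is refused.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    shifted = t - tau
    if shifted <= 0:
        return float(history_value)
    if shifted > trajectory.t[-1] + 1e-12:
        raise ValueError(
            f"t - tau = {shifted:.4g} h exceeds the stored grid end "
            f"{trajectory.t[-1]:.4g} h (extrapolation forbidden)"
        )
    return trajectory.tnf_at(shifted)


# ---------------------------------------------------------------------------
# Semi-analytic fast path (k_out_inos = k_out_no = 0)
# ---------------------------------------------------------------------------

_RATE_EPS = 1e-10  # below this a first-order rate is treated as zero


def _il6_closed_form(params: PDParameters, conc: float, t: np.ndarray) -> np.ndarray:
    """Piecewise closed-form IL-6 under the exact delayed TNF-α forcing."""
    ki, ko, tau = params.k_in_il6, params.k_out_il6, params.tau1
    s = params.k_in_tnf * (1.0 - drug_effect(params.alpha, conc))
    k = params.k_out_tnf
    tnf0, y0 = params.tnf0, params.il6_0

    # segment 1 (constant forcing ki*tnf0), evaluated at min(t, tau)
    m = np.minimum(t, tau)
    if ko > _RATE_EPS:
        p1 = ki * tnf0 / ko
        seg1 = p1 + (y0 - p1) * np.exp(-ko * m)
        y_tau = p1 + (y0 - p1) * math.exp(-ko * tau)
    else:
        seg1 = y0 + ki * tnf0 * m
        y_tau = y0 + ki * tnf0 * tau

    u = np.maximum(t - tau, 0.0)
    if k > _RATE_EPS:
        a = s / k
        b = tnf0 - a
        if ko > _RATE_EPS:
            if abs(ko - k) > 1e-9 * max(ko, k):
                part = ki * a / ko + ki * b / (ko - k) * np.exp(-k * u)
                d = y_tau - (ki * a / ko + ki * b / (ko - k))
                seg2 = part + d * np.exp(-ko * u)
            else:  # resonant limit ko -> k
                seg2 = (
                    ki * a / ko
                    + ki * b * u * np.exp(-k * u)
                    + (y_tau - ki * a / ko) * np.exp(-ko * u)
                )
        else:
            seg2 = y_tau + ki * (a * u + b / k * (1.0 - np.exp(-k * u)))
    else:  # TNF linear in time: forcing ki*(tnf0 + s*u)
        if ko > _RATE_EPS:
            q = ki * s / ko
            p = (ki * tnf0 - q) / ko
            seg2 = p + q * u + (y_tau - p) * np.exp(-ko * u)
        else:
            seg2 = y_tau + ki * (tnf0 * u + 0.5 * s * u * u)
    return np.where(t > tau, seg2, seg1)


def _delayed_tnf_integral(params: PDParameters, conc: float, t: np.ndarray, tau: float):
    """∫₀ᵗ TNF(s - tau) ds with constant history tnf0."""
    s = params.k_in_tnf * (1.0 - drug_effect(params.alpha, conc))
    k = params.k_out_tnf
    tnf0 = params.tnf0
    m = np.minimum(t, tau)
    u = np.maximum(t - tau, 0.0)
    if k > _RATE_EPS:
        a = s / k
        b = tnf0 - a
        tail = a * u + b / k * (1.0 - np.exp(-k * u))
    else:
        tail = tnf0 * u + 0.5 * s * u * u
    return tnf0 * m + tail


def _inos_closed_form(params: PDParameters, conc: float, t: np.ndarray) -> np.ndarray:
    """iNOS with k_out_inos = 0: inos0 + k_in_inos * ∫ delayed TNF."""
    return params.inos0 + params.k_in_inos * _delayed_tnf_integral(
        params, conc, t, params.tau2
    )


def _no_closed_form(params: PDParameters, conc: float, t: np.ndarray) -> np.ndarray:
    """NO with k_out_no = 0: no0 + k_in_no * ∫ iNOS**delta.

    On [0, tau2] iNOS is linear in time and the power integral is exact; past
    tau2 the smooth integrand is handled by 48-point Gauss–Legendre.
    """
    delta = params.delta
    c = params.k_in_inos * params.tnf0
    tau = params.tau2
    m = np.minimum(t, tau)
    if c > 0:
        head = ((params.inos0 + c * m) ** (delta + 1.0) - params.inos0 ** (delta + 1.0)) / (
            c * (delta + 1.0)
        )
    else:
        head = params.inos0**delta * m

    u = np.maximum(t - tau, 0.0)
    # map Gauss-Legendre nodes onto [tau, t] for each output time
    half = 0.5 * u[:, None]
    nodes = tau + half * (_GL_NODES[None, :] + 1.0)
    vals = _inos_closed_form(params, conc, nodes.ravel()).reshape(nodes.shape)
    tail = half[:, 0] * (vals**delta @ _GL_WEIGHTS)
    return params.no0 + params.k_in_no * (head + np.where(t > tau, tail, 0.0))


def predict_states(params: PDParameters, conc: float, t) -> dict[str, np.ndarray]:
    """Semi-analytic state predictions; requires k_out_inos = k_out_no = 0."""
    if params.k_out_inos != 0.0 or params.k_out_no != 0.0:
        raise ValueError(
            "semi-analytic path requires k_out_inos = k_out_no = 0; "
            "use simulate_cascade instead"
        )
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return {
        "TNF": tnf_closed_form(params, conc, t),
        "IL6": _il6_closed_form(params, conc, t),
        "iNOS": _inos_closed_form(params, conc, t),
        "NO": _no_closed_form(params, conc, t),
    }


# ---------------------------------------------------------------------------
# General numerical integration
# ---------------------------------------------------------------------------


def simulate_cascade(
    params: PDParameters,
    conc: float,
    grid,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full cascade for one arm on the given time grid.

    TNF-α is autonomous and evaluated from its closed form (so the delayed
    lookups TNF(t - tau) are exact); IL-6, iNOS and NO are integrated
    numerically.  Any state dipping below -1e-9 raises; tiny negative
    round-off is clipped to 0 with a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or grid[0] != 0.0:
        raise ValueError("grid must be 1-D and start at 0")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    params.check_arms([conc])

    tnf = tnf_closed_form(params, conc, grid)

    def rhs(t, y):
        il6, inos, no = y
        tnf_t1 = tnf_delayed(params, conc, t, params.tau1)
        tnf_t2 = tnf_delayed(params, conc, t, params.tau2)
        return [
            params.k_in_il6 * tnf_t1 - params.k_out_il6 * il6,
            params.k_in_inos * tnf_t2 - params.k_out_inos * inos,
            params.k_in_no * max(inos, 0.0) ** params.delta - params.k_out_no * no,
        ]

    y0 = [params.il6_0, params.inos0, params.no0]
    if grid.size == 1:
        sol_y = np.array(y0, dtype=float)[:, None]
    else:
        sol = solve_ivp(
            rhs,
            (0.0, grid[-1]),
            y0,
            t_eval=grid,
            rtol=rtol,
            atol=atol,
            method=method,
        )
        if not sol.success:
            raise RuntimeError(f"cascade integration failed: {sol.message}")
        sol_y = sol.y

    states = np.vstack([tnf, sol_y])
    if np.any(states < -1e-9):
        raise RuntimeError(
            f"negative state (min {states.min():.3g}) beyond round-off tolerance"
        )
    if np.any(states < 0):
        logger.warning("clipping tiny negative states (min %.3g) to 0", states.min())
        states = np.clip(states, 0.0, None)

    return Trajectory(
        conc=conc,
        t=grid,
        tnf=states[0],
        il6=states[1],
        inos=states[2],
        no=states[3],
    )
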