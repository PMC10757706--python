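"""Surrogate ODE models of cell-cycle growth and chemotherapy response.

Control (untreated) model: two compartments, cycling G1/S cells (``N_1S``)
and cycling G2/M cells (``N_2M``)::

    dN_1S/dt = -lam*N_1S + alpha*(2 - (N_1S+N_2M)/K)*N_2M
    dN_2M/dt =  lam*N_1S - alpha*N_2M

G1/S cells enter G2/M at rate ``lam``; G2/M cells divide at rate ``alpha``,
producing between 2 daughters (empty dish) and 1 (dish at carrying capacity
``K``, i.e. crowded cells re-enter G1/S without dividing).

Treatment model: two extra absorbing compartments of arrested cells,
``A_1S`` and ``A_2M``.  Cycling cells arrest at the G1/S and G2/M
checkpoints at Hill-saturating, dose-dependent rates (maximum rates
``beta_1S``/``beta_2M``, shared EC50 ``kappa_beta`` and Hill coefficient
``m``); arrested cells die at a saturating rate (maximum ``delta``, EC50
``kappa_delta``, unit Hill coefficient).  ``N = N_1S+N_2M+A_1S+A_2M`` is the
total number of alive cells; the flow-cytometry-style observable is the G2/M
fraction ``(N_2M + A_2M)/N``.

The public :func:`solve` uses an adaptive Runge-Kutta integrator
(``scipy.integrate.solve_ivp``).  Calibration loops use a jitted fixed-step
RK4 fast path (:func:`solve_fast`), cross-checked against the adaptive
solver in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp


class IntegrationError(RuntimeError):
    """Raised when the adaptive solver fails to reach the end of the grid."""


def hill(C: float, ec50: float, exponent: float = 1.0) -> float:
    """Saturating Hill factor ``C^m / (ec50^m + C^m)``, with ``hill(0) = 0``.

    The zero-dose value is pinned to 0 by convention (no drug, no effect)
    so that the limit ``m -> 0`` cannot produce a spurious 1/2 at C=0.
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if C < 0:
        raise ValueError("concentration must be nonnegative")
    if C == 0:
        return 0.0
    cm = C**exponent
    return cm / (ec50**exponent + cm)


@dataclass(frozen=True)
class SMControlParams:
    """Control surrogate parameters (all per hour except ``K`` in cells)."""

    lam: float    # G1/S -> G2/M transition rate
    alpha: float  # G2/M -> G1/S division rate
    K: float      # carrying capacity of the dish

    def __post_init__(self):
        if not (self.lam > 0 and self.alpha > 0 and self.K > 0):
            raise ValueError("lam, alpha, K must be strictly positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SMTreatmentParams(SMControlParams):
    """Treatment surrogate parameters: control + arrest/apoptosis terms."""

    beta_1S: float = 0.0      # max arrest rate out of G1/S, /h
    beta_2M: float = 0.0      # max arrest rate out of G2/M, /h
    kappa_beta: float = 1.0   # EC50 of both arrest rates, uM
    m: float = 1.0            # arrest Hill coefficient
    delta: float = 0.0        # max apoptosis rate of arrested cells, /h
    kappa_delta: float = 1.0  # EC50 of the apoptosis rate, uM

    def __post_init__(self):
        super().__post_init__()
        if self.beta_1S < 0 or self.beta_2M < 0 or self.delta < 0:
            raise ValueError("beta_1S, beta_2M, delta must be nonnegative")
        if self.kappa_beta <= 0 or self.kappa_delta <= 0:
            raise ValueError("kappa_beta, kappa_delta must be positive")
        if self.m < 0:
            raise ValueError("m must be nonnegative")


def control_rhs(state: Sequence[float], p: SMControlParams) -> np.ndarray:
    """Right-hand side of the control model at ``state = (N_1S, N_2M)``."""
    n1, n2 = state
    total = n1 + n2
    return np.array(
        [
            -p.lam * n1 + p.alpha * (2.0 - total / p.K) * n2,
            p.lam * n1 - p.alpha * n2,
        ]
    )


def treatment_rhs(state: Sequence[float], p: SMTreatmentParams, C: float) -> np.ndarray:
    """Right-hand side of the treatment model at ``state = (N_1S, N_2M, A_1S, A_2M)``."""
    n1, n2, a1, a2 = state
    total = n1 + n2 + a1 + a2
    h_arrest = hill(C, p.kappa_beta, p.m)
    h_death = hill(C, p.kappa_delta, 1.0)
    b1 = p.beta_1S * h_arrest
    b2 = p.beta_2M * h_arrest
    d = p.delta * h_death
    return np.array(
        [
            -p.lam * n1 + p.alpha * (2.0 - total / p.K) * n2 - b1 * n1,
            p.lam * n1 - p.alpha * n2 - b2 * n2,
            b1 * n1 - d * a1,
            b2 * n2 - d * a2,
        ]
    )


def stationary_split(lam: float, alpha: float) -> float:
    """Exponential-growth G1/S share ``q`` of the uncrowded linear cycle.

    The linear part of the control model is ``[[-lam, 2*alpha], [lam, -alpha]]``;
    its dominant eigenvector gives the asymptotic split between cycling
    compartments, used as the default t=0 split when only a total count is known.
    """
    A = np.array([[-lam, 2.0 * alpha], [lam, -alpha]])
    w, v = np.linalg.eig(A)
    vec = np.abs(v[:, np.argmax(w.real)].real)
    return float(vec[0] / vec.sum())


def _full_state(init, n_compartments: int) -> np.ndarray:
    y0 = np.zeros(4)
    init = np.asarray(init, dtype=float)
    y0[: init.size] = init
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    return y0 if n_compartments == 4 else y0[:2]


def solve(
    params: SMControlParams,
    init: Sequence[float],
    t_grid: Sequence[float],
    C: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
) -> pd.DataFrame:
    """Integrate the surrogate model and evaluate it on ``t_grid``.

    ``params`` selects the model: a plain :class:`SMControlParams` integrates
    the two-compartment control system; :class:`SMTreatmentParams` integrates
    the four-compartment treatment system at dose ``C``.

    Returns a tidy frame with columns ``time_h, dose_uM, N1S, N2M, A1S, A2M,
    N, g2m_fraction``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a nonempty 1-D array")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    treated = isinstance(params, SMTreatmentParams)
    ncomp = 4 if treated else 2
    y0 = _full_state(init, ncomp)

    if treated:
        fun = lambda t, y: treatment_rhs(y, params, C)
    else:
        fun = lambda t, y: control_rhs(y, params)

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        fun, (t0, t_grid[-1]), y0, t_eval=t_grid, rtol=rtol, atol=atol, method=method
    )
    if not sol.success:
        raise IntegrationError(f"surrogate integration failed: {sol.message}")
    y = sol.y
    if ncomp == 2:
        y = np.vstack([y, np.zeros((2, y.shape[1]))])
    return _trajectory_frame(t_grid, C, y.T)


def _trajectory_frame(t_grid: np.ndarray, C: float, y: np.ndarray) -> pd.DataFrame:
    n1, n2, a1, a2 = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
    total = n1 + n2 + a1 + a2
    with np.errstate(divide="ignore", invalid="ignore"):
        g2m = np.where(total > 0, (n2 + a2) / total, np.nan)
    return pd.DataFrame(
        {
            "time_h": t_grid,
            "dose_uM": C,
            "N1S": n1,
            "N2M": n2,
            "A1S": a1,
            "A2M": a2,
            "N": total,
            "g2m_fraction": g2m,
        }
    )


# ----------------------------------------------------------------- fast path


@njit(cache=True)
def _rk4_kernel(lam, alpha, K, b1, b2, d, y0, t_eval, dt):  # pragma: no cover - jitted
    """Fixed-step RK4 for the 4-compartment system with dose-collapsed rates.

    ``b1``/``b2``/``d`` are the arrest and death fluxes after the (constant-
    in-time) Hill factors have been folded in, so the same kernel serves
    control (b1=b2=d=0) and treatment.
    """
    n_out = t_eval.shape[0]
    out = np.empty((n_out, 4))
    y = y0.copy()
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    yt = np.empty(4)
    t = 0.0
    for i in range(n_out):
        t_target = t_eval[i]
        span = t_target - t
        if span > 0:
            n_steps = int(np.ceil(span / dt))
            h = span / n_steps
            for _ in range(n_steps):
                _rhs_inplace(y, lam, alpha, K, b1, b2, d, k1)
                for j in range(4):
                    yt[j] = y[j] + 0.5 * h * k1[j]
                _rhs_inplace(yt, lam, alpha, K, b1, b2, d, k2)
                for j in range(4):
                    yt[j] = y[j] + 0.5 * h * k2[j]
                _rhs_inplace(yt, lam, alpha, K, b1, b2, d, k3)
                for j in range(4):
                    yt[j] = y[j] + h * k3[j]
                _rhs_inplace(yt, lam, alpha, K, b1, b2, d, k4)
                for j in range(4):
                    y[j] += h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            t = t_target
        for j in range(4):
            out[i, j] = y[j]
    return out


@njit(cache=True, inline="always")
def _rhs_inplace(y, lam, alpha, K, b1, b2, d, out):  # pragma: no cover - jitted
    total = y[0] + y[1] + y[2] + y[3]
    out[0] = -lam * y[0] + alpha * (2.0 - total / K) * y[1] - b1 * y[0]
    out[1] = lam * y[0] - alpha * y[1] - b2 * y[1]
    out[2] = b1 * y[0] - d * y[2]
    out[3] = b2 * y[1] - d * y[3]


def solve_fast(
    params: SMControlParams,
    init: Sequence[float],
    t_grid: Sequence[float],
    C: float = 0.0,
    dt: float = 0.05,
) -> np.ndarray:
    """Fixed-step RK4 trajectory, returned as an ``(n_times, 4)`` array.

    Columns are ``N1S, N2M, A1S, A2M``.  Used by the calibration inner loop;
    agreement with :func:`solve` is asserted in the test suite.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    y0 = _full_state(init, 4)
    if isinstance(params, SMTreatmentParams):
        h_arrest = hill(C, params.kappa_beta, params.m)
        h_death = hill(C, params.kappa_delta, 1.0)
        b1 = params.beta_1S * h_arrest
        b2 = params.beta_2M * h_arrest
        d = params.delta * h_death
    else:
        b1 = b2 = d = 0.0
    return _rk4_kernel(params.lam, params.alpha, params.K, b1, b2, d, y0, t_grid, dt)
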