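"""Weighted least-squares calibration of surrogate parameters.

The model object :class:`SurrogateCalibration` binds a surrogate family
(control or treatment) to a :class:`~smorepars.data.TimeSeriesDataset`;
``fit()`` runs a multi-start bound-constrained local optimization of the
weighted residual sum of squares

    RSS(theta) = sum_arms sum_t ((sim(t; theta) - mean(t)) / w(t))^2

and returns a :class:`CalibrationResults` carrying the estimates, the RSS
and its per-arm decomposition, and profile-likelihood accessors.

Weights ``w`` are the replicate SDs, floored point-wise at 5% of the data
mean at that time point (so the RSS behaves like a chi-square and the
profile-likelihood threshold is coherent); arms without SDs weight each
point by its own mean, i.e. relative error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import surrogate
from .data import TimeSeriesDataset

#: Default fit bounds per parameter.  Only the K upper bound (10,000 cells)
#: is treated as a hard modelling choice; the rest bracket plausible
#: per-hour rates and uM-scale EC50s and are overridable.
DEFAULT_BOUNDS = {
    "lam": (1e-3, 2.0),
    "alpha": (1e-3, 2.0),
    "K": (100.0, 10_000.0),
    "beta_1S": (0.0, 2.0),
    "beta_2M": (0.0, 2.0),
    "kappa_beta": (0.01, 50.0),
    "m": (0.1, 4.0),
    "delta": (0.0, 2.0),
    "kappa_delta": (0.01, 50.0),
    "q": (0.02, 0.98),
}

#: Parameters profiled / intersected in SM space, per model family.
SM_PARAM_NAMES = {
    "control": ("lam", "alpha", "K"),
    "treatment": (
        "lam", "alpha", "K",
        "beta_1S", "beta_2M", "kappa_beta", "m", "delta", "kappa_delta",
    ),
}

#: Parameters optimized on a log grid when profiled (scale parameters).
LOG_SCALE_PARAMS = frozenset({"K", "kappa_beta", "kappa_delta"})

_COMPARTMENT_OBS = ("g1s_count", "g2m_count")


class AlignmentError(KeyError):
    """A data (arm, time) point is missing from the simulated trajectory."""


class OptimizationError(RuntimeError):
    """All optimization starts failed."""


def arm_weights(arm, floor_frac: float = 0.05) -> np.ndarray:
    """Per-point weights for one arm.

    Replicate SDs, floored point-wise at ``floor_frac`` of the data mean at
    that time point (so a lucky near-zero SD estimate from few replicates
    cannot blow up a residual).  Arms without SDs weight each point by its
    own mean magnitude, i.e. relative error.
    """
    scale = np.maximum(np.abs(arm.mean), 1e-12)
    arm_scale = float(np.mean(np.abs(arm.mean))) or 1.0
    if arm.sd is None:
        return scale
    floor = np.maximum(floor_frac * scale, 1e-6 * arm_scale)
    return np.maximum(arm.sd, floor)


def weighted_rss(
    predictions: Mapping[tuple[float, str], np.ndarray],
    data: TimeSeriesDataset,
    floor_frac: float = 0.05,
    arm_multipliers: Mapping[tuple[float, str], float] | None = None,
) -> tuple[float, dict[tuple[float, str], float]]:
    """Weighted RSS of ``predictions`` against ``data``, with per-arm partial sums.

    ``predictions`` maps ``(dose, observable)`` to values aligned with that
    arm's time grid.  Returns ``(total, per_arm)``; the per-arm contributions
    sum exactly to the total.
    """
    total = 0.0
    per_arm: dict[tuple[float, str], float] = {}
    for arm in data:
        if arm.key not in predictions:
            raise AlignmentError(f"no prediction for arm {arm.key}")
        sim = np.asarray(predictions[arm.key], dtype=float)
        if sim.shape != arm.times.shape:
            raise AlignmentError(f"prediction for arm {arm.key} has wrong length")
        w = arm_weights(arm, floor_frac)
        mult = 1.0 if arm_multipliers is None else float(arm_multipliers.get(arm.key, 1.0))
        val = mult * float(np.sum(((sim - arm.mean) / w) ** 2))
        per_arm[arm.key] = val
        total += val
    return total, per_arm


class SurrogateCalibration:
    """Surrogate-model calibration problem bound to a dataset.

    Parameters
    ----------
    data :
        Multi-arm time-series dataset (experimental-style, synthetic, or
        ABM output converted via
        :func:`smorepars.abm.outputs_to_dataset`).
    model :
        ``"control"`` (3 surrogate parameters) or ``"treatment"`` (9).
    bounds :
        Per-parameter ``(lo, hi)`` overrides of :data:`DEFAULT_BOUNDS`.
    fit_initial_split :
        Whether the t=0 split ``q`` of the known initial total between the
        two cycling compartments is a free parameter.  Defaults to True when
        the data contain compartment-count arms (which pin it down) and
        False otherwise, in which case ``q`` is tied to the exponential-
        growth split implied by the current ``(lam, alpha)``.
    """

    def __init__(
        self,
        data: TimeSeriesDataset,
        model: str = "control",
        bounds: Mapping[str, tuple[float, float]] | None = None,
        fit_initial_split: bool | None = None,
        floor_frac: float = 0.05,
        arm_multipliers: Mapping[tuple[float, str], float] | None = None,
        solver_dt: float = 0.05,
    ):
        if model not in SM_PARAM_NAMES:
            raise ValueError("model must be 'control' or 'treatment'")
        self.data = data
        self.model = model
        self.floor_frac = floor_frac
        self.arm_multipliers = dict(arm_multipliers) if arm_multipliers else None
        self.solver_dt = solver_dt
        if fit_initial_split is None:
            fit_initial_split = any(a.observable in _COMPARTMENT_OBS for a in data)
        self.fit_initial_split = bool(fit_initial_split)
        names = list(SM_PARAM_NAMES[model])
        if self.fit_initial_split:
            names.append("q")
        self.param_names: tuple[str, ...] = tuple(names)
        self.sm_param_names: tuple[str, ...] = SM_PARAM_NAMES[model]
        self.bounds: dict[str, tuple[float, float]] = {
            n: tuple(DEFAULT_BOUNDS[n]) for n in self.param_names
        }
        if bounds:
            for n, b in bounds.items():
                if n in self.bounds:
                    self.bounds[n] = (float(b[0]), float(b[1]))
        self.n0 = float(data.initial_count)
        # per-dose union time grids and per-arm index maps
        self._dose_times: dict[float, np.ndarray] = {}
        self._arm_index: dict[tuple[float, str], np.ndarray] = {}
        for dose in data.doses:
            times = np.unique(
                np.concatenate([a.times for a in data if a.dose == dose])
            )
            self._dose_times[dose] = times
            for a in data:
                if a.dose == dose:
                    self._arm_index[a.key] = np.searchsorted(times, a.times)
        self._arm_w = {a.key: arm_weights(a, floor_frac) for a in data}

    # ------------------------------------------------------------- modelling

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, model: str = "control", **kw):
        """Build from a tidy frame with the dataset CSV schema."""
        return cls(TimeSeriesDataset.from_frame(frame), model=model, **kw)

    def _params_obj(self, theta: Mapping[str, float]) -> surrogate.SMTreatmentParams:
        if self.model == "control":
            return surrogate.SMTreatmentParams(
                lam=theta["lam"], alpha=theta["alpha"], K=theta["K"]
            )
        return surrogate.SMTreatmentParams(
            lam=theta["lam"], alpha=theta["alpha"], K=theta["K"],
            beta_1S=theta["beta_1S"], beta_2M=theta["beta_2M"],
            kappa_beta=theta["kappa_beta"], m=theta["m"],
            delta=theta["delta"], kappa_delta=theta["kappa_delta"],
        )

    def _initial_state(self, theta: Mapping[str, float]) -> np.ndarray:
        q = theta.get("q")
        if q is None:
            q = surrogate.stationary_split(theta["lam"], theta["alpha"])
        return np.array([q * self.n0, (1.0 - q) * self.n0, 0.0, 0.0])

    def predict(self, theta: Mapping[str, float] | Sequence[float]) -> dict:
        """Model predictions keyed by ``(dose, observable)`` at the arm times."""
        theta = self._as_dict(theta)
        params = self._params_obj(theta)
        y0 = self._initial_state(theta)
        out: dict[tuple[float, str], np.ndarray] = {}
        for dose, times in self._dose_times.items():
            y = surrogate.solve_fast(params, y0, times, C=dose, dt=self.solver_dt)
            n1, n2, a1, a2 = y[:, 0], y[:, 1], y[:, 2], y[:, 3]
            total = n1 + n2 + a1 + a2
            for arm in self.data:
                if arm.dose != dose:
                    continue
                idx = self._arm_index[arm.key]
                if arm.observable == "total_count":
                    vals = total[idx]
                elif arm.observable == "g1s_count":
                    vals = (n1 + a1)[idx]
                elif arm.observable == "g2m_count":
                    vals = (n2 + a2)[idx]
                elif arm.observable == "g2m_fraction":
                    with np.errstate(divide="ignore", invalid="ignore"):
                        vals = np.where(total > 0, (n2 + a2) / total, 0.0)[idx]
                else:  # pragma: no cover - validated upstream
                    raise AlignmentError(arm.observable)
                out[arm.key] = vals
        return out

    def _as_dict(self, theta) -> dict[str, float]:
        if isinstance(theta, Mapping):
            return dict(theta)
        theta = np.asarray(theta, dtype=float)
        return dict(zip(self.param_names, theta))

    def rss(self, theta) -> float:
        """Total weighted RSS at ``theta`` (dict or array in param order)."""
        return self.rss_decomposed(theta)[0]

    def rss_decomposed(self, theta) -> tuple[float, dict]:
        preds = self.predict(theta)
        return weighted_rss(
            preds, self.data, floor_frac=self.floor_frac, arm_multipliers=self.arm_multipliers
        )

    # ------------------------------------------------------------ optimization

    def _to_unit(self, x: np.ndarray, names: Sequence[str]) -> np.ndarray:
        z = np.empty(len(names))
        for i, n in enumerate(names):
            lo, hi = self.bounds[n]
            if n in LOG_SCALE_PARAMS:
                z[i] = np.log(x[i] / lo) / np.log(hi / lo)
            else:
                z[i] = (x[i] - lo) / (hi - lo)
        return z

    def _from_unit(self, z: np.ndarray, names: Sequence[str]) -> np.ndarray:
        x = np.empty(len(names))
        for i, n in enumerate(names):
            lo, hi = self.bounds[n]
            zi = min(1.0, max(0.0, z[i]))
            if n in LOG_SCALE_PARAMS:
                x[i] = lo * (hi / lo) ** zi
            else:
                x[i] = lo + zi * (hi - lo)
        return x

    def _minimize(
        self,
        z0: np.ndarray,
        names: Sequence[str],
        fixed: Mapping[str, float] | None = None,
        maxiter: int = 200,
    ):
        fixed = dict(fixed or {})

        def fun(z):
            x = self._from_unit(z, names)
            theta = dict(zip(names, x))
            theta.update(fixed)
            try:
                return self.rss_decomposed(theta)[0]
            except (FloatingPointError, ValueError):  # pragma: no cover - guard
                return 1e12

        res = minimize(
            fun,
            np.clip(z0, 0.0, 1.0),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(names),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
        )
        return res

    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        x0: Mapping[str, float] | None = None,
        maxiter: int = 200,
    ) -> "CalibrationResults":
        """Multi-start bound-constrained fit; deterministic given ``seed``.

        ``x0`` adds one user-supplied start to the Latin-hypercube starts.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        names = self.param_names
        sampler = qmc.LatinHypercube(d=len(names), seed=int(seed) % (2**31))
        starts = [sampler.random(1)[0] for _ in range(n_starts)]
        if x0 is not None:
            x0_arr = np.array([x0[n] for n in names], dtype=float)
            starts.insert(0, self._to_unit(x0_arr, names))
        best = None
        n_ok = 0
        for z0 in starts:
            try:
                res = self._minimize(z0, names, maxiter=maxiter)
            except Exception:  # pragma: no cover - optimizer guard
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise OptimizationError("all optimization starts failed")
        x = self._from_unit(best.x, names)
        theta = dict(zip(names, x))
        rss, per_arm = self.rss_decomposed(theta)
        return CalibrationResults(
            model=self,
            params=theta,
            rss=rss,
            per_arm_rss=per_arm,
            converged=bool(best.success) and n_ok > 0,
            bounds=dict(self.bounds),
            n_starts=n_starts,
            seed=seed,
        )


@dataclass
class CalibrationResults:
    """Best-fit surrogate parameters and fit diagnostics.

    Profile-likelihood confidence intervals are available through
    :meth:`profile` / :meth:`profile_all` (see
    :mod:`smorepars.identifiability`).
    """

    model: SurrogateCalibration
    params: dict[str, float]
    rss: float
    per_arm_rss: dict[tuple[float, str], float]
    converged: bool
    bounds: dict[str, tuple[float, float]]
    n_starts: int
    seed: int

    @property
    def x(self) -> np.ndarray:
        return np.array([self.params[n] for n in self.model.param_names])

    @property
    def n_obs(self) -> int:
        return int(sum(a.times.size for a in self.model.data))

    def predict(self) -> dict:
        return self.model.predict(self.params)

    def simulate(self, t_grid: Sequence[float], C: float = 0.0) -> pd.DataFrame:
        """Adaptive-solver trajectory of the fitted surrogate at dose ``C``."""
        theta = self.params
        params = self.model._params_obj(theta)
        return surrogate.solve(params, self.model._initial_state(theta), t_grid, C=C)

    def profile(self, name: str, **kw):
        from .identifiability import profile_parameter

        return profile_parameter(self, name, **kw)

    def profile_all(self, names: Sequence[str] | None = None, **kw) -> dict:
        """Profile every surrogate parameter (``q`` is a nuisance, not profiled)."""
        names = names or self.model.sm_param_names
        return {n: self.profile(n, **kw) for n in names}

    def summary(self) -> str:
        lines = [
            "Surrogate calibration results",
            "=" * 46,
            f"model:      {self.model.model}",
            f"arms:       {len(self.model.data)}   n_obs: {self.n_obs}",
            f"weighted RSS: {self.rss:.6g}   converged: {self.converged}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'lower bnd':>11}{'upper bnd':>11}",
        ]
        for n in self.model.param_names:
            lo, hi = self.bounds[n]
            lines.append(f"{n:<12}{self.params[n]:>12.5g}{lo:>11.4g}{hi:>11.4g}")
        lines.append("-" * 46)
        lines.append("per-arm RSS:")
        for (dose, obs), v in sorted(self.per_arm_rss.items()):
            lines.append(f"  dose {dose:g} uM  {obs:<14} {v:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.model,
            "params": self.params,
            "rss": self.rss,
            "per_arm_rss": {f"{d}|{o}": v for (d, o), v in self.per_arm_rss.items()},
            "converged": self.converged,
            "bounds": {n: list(b) for n, b in self.bounds.items()},
            "n_starts": self.n_starts,
            "seed": self.seed,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def fit_grid(
    datasets: Mapping[str, TimeSeriesDataset],
    model: str = "control",
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 20,
    rng_seed: int = 0,
    cache_dir: str | Path | None = None,
    **kw,
) -> tuple[dict[str, CalibrationResults], dict[str, str]]:
    """Independent surrogate fits to each keyed dataset (one per ABM vector).

    Results are cached as JSON per key when ``cache_dir`` is given, so an
    interrupted sweep resumes.  Returns ``(results, failures)``; per-vector
    failures are recorded, not fatal.
    """
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    results: dict[str, CalibrationResults] = {}
    failures: dict[str, str] = {}
    for i, key in enumerate(sorted(datasets)):
        calib = SurrogateCalibration(datasets[key], model=model, bounds=bounds, **kw)
        cache_file = cache / f"fit_{key}.json" if cache is not None else None
        if cache_file is not None and cache_file.exists():
            blob = json.loads(cache_file.read_text())
            theta = blob["params"]
            rss, per_arm = calib.rss_decomposed(theta)
            results[key] = CalibrationResults(
                model=calib, params=theta, rss=rss, per_arm_rss=per_arm,
                converged=blob["converged"], bounds=dict(calib.bounds),
                n_starts=blob["n_starts"], seed=blob["seed"],
            )
            continue
        seed_i = int(np.random.SeedSequence([int(rng_seed), i]).generate_state(1)[0] % (2**31))
        try:
            res = calib.fit(n_starts=n_starts, seed=seed_i)
        except OptimizationError as exc:
            warnings.warn(f"fit failed for vector {key}: {exc}")
            failures[key] = str(exc)
            continue
        results[key] = res
        if cache_file is not None:
            res.save_json(cache_file)
    return results, failures


def grid_summary(results: Mapping[str, CalibrationResults]) -> pd.DataFrame:
    """One row per ABM vector: fitted parameters and RSS."""
    rows = []
    for key in sorted(results):
        r = results[key]
        rows.append({"vector_id": key, **r.params, "rss": r.rss, "converged": r.converged})
    return pd.DataFrame(rows)
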