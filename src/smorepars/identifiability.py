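"""Profile-likelihood identifiability analysis.

Each fitted parameter is "profiled": fixed across a grid of values while all
remaining parameters are re-optimized (warm-started from the neighboring
grid point).  The resulting curve of re-optimized weighted RSS values is the
likelihood profile; its crossings of the threshold

    RSS_min + chi2_quantile(level, df=1)

give the confidence bounds (Venzon-Moolgavkar practice; with SD-weighted
residuals the weighted RSS behaves as a chi-square up to a constant).  A
profile that reaches the parameter bound before crossing is flagged
unbounded on that side - practical non-identifiability.

The co-fitted values of all other parameters along a profile trace a path
through full parameter space; the union of these paths, truncated at the
threshold, is the practically identifiable combination used as the
data-informed set Psi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calibration import CalibrationResults, LOG_SCALE_PARAMS

#: Endpoint flags.
CROSSED = "crossed"
UNBOUNDED = "at_bound_unbounded"


def ci_threshold(rss_min: float, level: float = 0.95) -> float:
    """Profile-likelihood threshold ``RSS_min + chi2.ppf(level, df=1)``."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    return float(rss_min) + float(chi2.ppf(level, df=1))


@dataclass
class ProfileResult:
    """Likelihood profile of one parameter.

    ``values`` (ascending) are the fixed grid values, ``rss`` the
    re-optimized weighted RSS at each, and ``path`` the full co-fitted
    parameter vectors (one row per grid value, columns ``param_names``).
    """

    name: str
    param_names: tuple[str, ...]
    values: np.ndarray
    rss: np.ndarray
    path: np.ndarray
    rss_min: float
    threshold: float
    level: float
    ci: tuple[float, float]
    flags: tuple[str, str]
    best_value: float
    failures: int = 0

    @property
    def lower_unbounded(self) -> bool:
        return self.flags[0] == UNBOUNDED

    @property
    def upper_unbounded(self) -> bool:
        return self.flags[1] == UNBOUNDED

    def truncated_path(self) -> np.ndarray:
        """Path points with profile RSS <= threshold (the Psi polyline)."""
        keep = self.rss <= self.threshold + 1e-12
        return self.path[keep]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.path, columns=list(self.param_names))
        df.insert(0, "profiled_value", self.values)
        df["rss"] = self.rss
        return df

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "param_names": list(self.param_names),
            "values": self.values.tolist(),
            "rss": self.rss.tolist(),
            "path": self.path.tolist(),
            "rss_min": self.rss_min,
            "threshold": self.threshold,
            "level": self.level,
            "ci": list(self.ci),
            "flags": list(self.flags),
            "best_value": self.best_value,
            "failures": self.failures,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileResult":
        return cls(
            name=d["name"],
            param_names=tuple(d["param_names"]),
            values=np.asarray(d["values"], dtype=float),
            rss=np.asarray(d["rss"], dtype=float),
            path=np.asarray(d["path"], dtype=float),
            rss_min=d["rss_min"],
            threshold=d["threshold"],
            level=d["level"],
            ci=tuple(d["ci"]),
            flags=tuple(d["flags"]),
            best_value=d["best_value"],
            failures=d.get("failures", 0),
        )


def _use_log_grid(name: str, lo: float, hi: float) -> bool:
    """Log-spaced profile grid for positive parameters with wide bounds.

    Scale parameters are always profiled on a log grid; any positive
    parameter whose bounds span more than two decades (e.g. a rate bounded
    in [1e-3, 2]) also is, since a linear grid would leave the low decades
    unresolved.
    """
    if name in LOG_SCALE_PARAMS:
        return True
    return lo > 0 and hi / lo > 100


def _side_grid(best: float, bound: float, n: int, log_scale: bool) -> np.ndarray:
    """Grid from ``best`` (exclusive) towards ``bound`` (inclusive)."""
    if np.isclose(best, bound, rtol=1e-12, atol=0.0):
        return np.empty(0)
    if log_scale and best > 0 and bound > 0:
        return np.geomspace(best, bound, n + 1)[1:]
    return np.linspace(best, bound, n + 1)[1:]


def profile_parameter(
    fit: CalibrationResults,
    name: str,
    n_side: int = 20,
    level: float = 0.95,
    stop_margin: int = 3,
    maxiter: int = 60,
) -> ProfileResult:
    """Profile ``name`` around its best-fit value.

    ``n_side`` grid points per side span the optimum-to-bound interval
    (log-spaced for scale parameters and for any positive parameter with
    bounds spanning over two decades, linear otherwise); the sweep on each
    side stops ``stop_margin`` points after crossing the threshold or at the
    bound, re-optimizing all other parameters at each point with a warm
    start from the previous grid point.

    Each CI endpoint is localized by bisecting the bracketing grid interval
    with further re-optimizations, then linearly interpolating the profile
    across the final bracket; an endpoint that hits the bound before
    crossing is flagged ``at_bound_unbounded``.
    """
    model = fit.model
    if name not in model.param_names:
        raise KeyError(f"unknown parameter {name!r}")
    names = list(model.param_names)
    free = [n for n in names if n != name]
    lo, hi = model.bounds[name]
    best_val = float(fit.params[name])
    rss_min = float(fit.rss)
    threshold = ci_threshold(rss_min, level)
    log_scale = _use_log_grid(name, lo, hi)
    z_best = (
        model._to_unit(np.array([fit.params[n] for n in free]), free) if free else None
    )

    def reopt(v, z_warm):
        """Re-optimize the free parameters at fixed value ``v``."""
        if not free:
            return model.rss({name: v}), None, {name: v}
        res = model._minimize(z_warm, free, fixed={name: v}, maxiter=maxiter)
        theta = dict(zip(free, model._from_unit(res.x, free)))
        theta[name] = v
        return float(res.fun), res.x, theta

    def sweep(bound: float):
        grid = _side_grid(best_val, bound, n_side, log_scale)
        vals, rsses, paths, warms = [], [], [], []
        z_warm = z_best
        n_fail = 0
        crossed_at = None
        for k, v in enumerate(grid):
            r, z_new, theta = reopt(v, z_warm)
            if not np.isfinite(r):
                n_fail += 1
                continue
            z_warm = z_new if z_new is not None else None
            vals.append(v)
            rsses.append(r)
            paths.append([theta[n] for n in names])
            warms.append(z_warm)
            if r > threshold and crossed_at is None:
                crossed_at = k
            if crossed_at is not None and len(vals) >= crossed_at + 1 + stop_margin:
                break
        return vals, rsses, np.array(paths).reshape(-1, len(names)), warms, n_fail

    lo_vals, lo_rss, lo_path, lo_warm, f1 = sweep(lo)
    hi_vals, hi_rss, hi_path, hi_warm, f2 = sweep(hi)

    center_path = np.array([[fit.params[n] for n in names]])
    values = np.concatenate([lo_vals[::-1], [best_val], hi_vals])
    rss = np.concatenate([lo_rss[::-1], [rss_min], hi_rss])
    path = np.concatenate([lo_path[::-1], center_path, hi_path], axis=0)

    def refine(v_in, r_in, z_in, v_out, r_out, n_bisect=6):
        """Bisect the bracketing interval [inside, outside] of the crossing,
        re-optimizing at each midpoint (geometric midpoints on log grids);
        finish with linear interpolation on the final bracket."""
        a, ra, z = v_in, r_in, z_in
        b, rb = v_out, r_out
        for _ in range(n_bisect):
            if log_scale and a > 0 and b > 0:
                mid = float(np.sqrt(a * b))
            else:
                mid = 0.5 * (a + b)
            r_mid, z_mid, _ = reopt(mid, z)
            if r_mid > threshold:
                b, rb = mid, r_mid
            else:
                a, ra = mid, r_mid
                if z_mid is not None:
                    z = z_mid
        frac = (threshold - ra) / (rb - ra)
        return a + frac * (b - a)

    def endpoint(side_vals, side_rss, side_warm, bound):
        """Walk outward from the optimum to the first threshold crossing."""
        prev_v, prev_r, prev_z = best_val, rss_min, z_best
        for k, (v, r) in enumerate(zip(side_vals, side_rss)):
            if r > threshold:
                return refine(prev_v, prev_r, prev_z, v, r), CROSSED
            prev_v, prev_r = v, r
            prev_z = side_warm[k]
        return bound, UNBOUNDED

    ci_lo, flag_lo = endpoint(lo_vals, lo_rss, lo_warm, lo)
    ci_hi, flag_hi = endpoint(hi_vals, hi_rss, hi_warm, hi)

    return ProfileResult(
        name=name,
        param_names=tuple(names),
        values=values,
        rss=rss,
        path=path,
        rss_min=rss_min,
        threshold=threshold,
        level=level,
        ci=(float(ci_lo), float(ci_hi)),
        flags=(flag_lo, flag_hi),
        best_value=best_val,
        failures=f1 + f2,
    )


@dataclass
class IdentifiableCombination:
    """Union of threshold-truncated profile paths in full parameter space.

    One polyline per profiled parameter; by construction the projection of
    each polyline onto its profiled axis is that parameter's confidence
    interval.
    """

    param_names: tuple[str, ...]
    polylines: list[np.ndarray]
    profiled: tuple[str, ...]

    def pairwise_curve(self, profiled: str, other: str) -> tuple[np.ndarray, np.ndarray]:
        """Co-fitted values of ``other`` vs the grid of ``profiled``.

        The relationship curves used to diagnose pairwise combination
        structure (largely coincident curves indicate a combination).
        """
        i = self.profiled.index(profiled)
        poly = self.polylines[i]
        jx = self.param_names.index(profiled)
        jy = self.param_names.index(other)
        return poly[:, jx], poly[:, jy]


def extract_combinations(
    profiles: Mapping[str, ProfileResult] | Sequence[ProfileResult],
    sm_names: Sequence[str] | None = None,
) -> IdentifiableCombination:
    """Build the identifiable-combination object from per-parameter profiles.

    ``sm_names`` restricts the coordinates kept (e.g. dropping a nuisance
    initial-split parameter from the geometric set).
    """
    if isinstance(profiles, Mapping):
        plist = [profiles[k] for k in profiles]
    else:
        plist = list(profiles)
    if not plist:
        raise ValueError("no profiles supplied")
    full_names = plist[0].param_names
    for p in plist:
        if p.param_names != full_names:
            raise ValueError("profiles computed against different parameterizations")
    keep_names = tuple(sm_names) if sm_names is not None else full_names
    cols = [full_names.index(n) for n in keep_names]
    polylines = [p.truncated_path()[:, cols] for p in plist]
    return IdentifiableCombination(
        param_names=keep_names,
        polylines=polylines,
        profiled=tuple(p.name for p in plist),
    )
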