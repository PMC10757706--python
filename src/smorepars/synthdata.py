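"""Synthetic datasets and ABM parameter grids.

The experimental structure emulated here is a growth-inhibition assay on a
cultured cancer cell line: viable-cell counts (normalized to 100 cells at
t=0) at five time points {10, 24, 36, 48, 72} h under three constant drug
doses {0, 0.75, 7.55} uM, plus flow-cytometry G2/M fractions for the two
treated arms only (cycle distributions are not measured in the control
arm).  No public machine-readable version of such data exists, so
:func:`generate_dataset` produces pseudo-experimental datasets with exactly
this shape from a known generating model (ABM or surrogate) plus
multiplicative lognormal replicate noise.

:func:`make_grid` builds the full-factorial low/medium/high ABM parameter
grids (3^7 control, 3^5 treatment) and :func:`run_grid` simulates the ABM
over a grid with disk caching, so interrupted sweeps resume.

The default level values are artifact defaults bracketing biologically
plausible ranges (phase dwell times spanning roughly half to double a ~24 h
cycle; EC50 levels bracketing the assay doses); they are not literature
values and are all overridable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abm, surrogate
from .data import Arm, TimeSeriesDataset

LEVEL_LABELS = ("low", "medium", "high")

DEFAULT_TIMES = (10.0, 24.0, 36.0, 48.0, 72.0)
DEFAULT_DOSES = (0.0, 0.75, 7.55)

#: Artifact-default control grid levels (overridable).
DEFAULT_CONTROL_LEVELS: dict[str, tuple[float, float, float]] = {
    "K_A": (1600, 2500, 3600),
    "T_con": (1, 2, 3),
    "s": (0.0, 1.0, 4.0),
    "rho_G1S": (1 / 22, 1 / 11, 2 / 11),
    "rho_SG2": (1 / 16, 1 / 8, 1 / 4),
    "rho_G2M": (1 / 8, 1 / 4, 1 / 2),
    "rho_MG1": (0.5, 1.0, 2.0),
}

#: Artifact-default treatment grid levels (overridable).
DEFAULT_TREATMENT_LEVELS: dict[str, tuple[float, float, float]] = {
    "r_G1": (0.2, 0.5, 0.8),
    "r_G2": (0.2, 0.5, 0.8),
    "gamma1": (0.5, 2.0, 8.0),
    "delta_p": (0.01, 0.03, 0.09),
    "gamma2": (0.5, 2.0, 8.0),
}


@dataclass(frozen=True)
class GridSpec:
    """Per-parameter low/medium/high levels plus simulation settings."""

    levels: dict[str, tuple[float, float, float]]
    doses: tuple[float, ...] = (0.0,)
    n_reps: int = 6
    t_grid: tuple[float, ...] = (0.0,) + DEFAULT_TIMES
    dt: float = 0.25
    n0: int = 100

    def __post_init__(self):
        for name, vals in self.levels.items():
            if len(vals) != 3:
                raise ValueError(f"parameter {name!r} must have exactly 3 levels")
            if not (vals[0] < vals[1] < vals[2]):
                raise ValueError(f"levels for {name!r} must be strictly increasing")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def n_vectors(self) -> int:
        return 3 ** len(self.levels)


def make_grid(spec: GridSpec) -> pd.DataFrame:
    """Full factorial grid in documented lexicographic order with stable ids.

    Parameters iterate in ``spec.levels`` key order with the first key
    outermost (slowest); ids are ``"v"``-prefixed zero-padded decimal ranks.
    Columns: the
    parameter values plus one ``level_<param>`` label column each.
    """
    names = list(spec.levels)
    width = len(str(spec.n_vectors - 1))
    rows = []
    for rank, combo in enumerate(itertools.product(range(3), repeat=len(names))):
        row = {"vector_id": "v" + str(rank).zfill(width)}
        for name, li in zip(names, combo):
            row[name] = spec.levels[name][li]
            row[f"level_{name}"] = LEVEL_LABELS[li]
        rows.append(row)
    return pd.DataFrame(rows)


def grid_levels(grid: pd.DataFrame) -> dict[str, dict[str, str]]:
    """Mapping vector_id -> {parameter: level label} for acceptance records."""
    out = {}
    level_cols = [c for c in grid.columns if c.startswith("level_")]
    for _, row in grid.iterrows():
        out[row["vector_id"]] = {c[len("level_"):]: row[c] for c in level_cols}
    return out


def _vector_params(
    row: Mapping[str, float],
    varied: Sequence[str],
    base_control: abm.ABMControlParams,
    base_treat: abm.ABMTreatmentParams | None,
) -> tuple[abm.ABMControlParams, abm.ABMTreatmentParams | None]:
    control_fields = set(base_control.to_dict())
    ctrl_kw = base_control.to_dict()
    treat_kw = base_treat.to_dict() if base_treat is not None else None
    for name in varied:
        v = row[name]
        if name in control_fields:
            ctrl_kw[name] = int(v) if name in ("K_A", "T_con") else float(v)
        elif treat_kw is not None and name in treat_kw:
            treat_kw[name] = float(v)
        else:
            raise KeyError(f"grid parameter {name!r} matches no ABM parameter")
    control = abm.ABMControlParams(**ctrl_kw)
    treat = abm.ABMTreatmentParams(**treat_kw) if treat_kw is not None else None
    return control, treat


def run_grid(
    spec: GridSpec,
    base_control: abm.ABMControlParams | None = None,
    base_treat: abm.ABMTreatmentParams | None = None,
    rng_seed: int = 0,
    cache_dir: str | Path | None = None,
    init_phases: str = "stationary",
) -> dict[str, list[abm.ABMOutput]]:
    """Simulate the ABM at every grid vector and dose, with disk caching.

    In a control study ``spec.levels`` vary control parameters and
    ``spec.doses`` is ``(0,)``.  In a treatment study the levels vary
    treatment parameters, ``base_control`` carries the fixed control vector
    (e.g. the mean of the control-study accepted set), and every vector is
    simulated at each dose.

    Returns ``{vector_id: [ABMOutput per dose]}``.  With ``cache_dir`` set,
    completed vectors are stored as JSON and reloaded on rerun, so
    interrupted sweeps resume without re-simulation.
    """
    base_control = base_control or abm.ABMControlParams()
    if base_treat is None and any(d > 0 for d in spec.doses):
        base_treat = abm.ABMTreatmentParams()
    grid = make_grid(spec)
    varied = list(spec.levels)
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    results: dict[str, list[abm.ABMOutput]] = {}
    for gi, row in grid.iterrows():
        vid = row["vector_id"]
        cache_file = cache / f"abm_{vid}.json" if cache is not None else None
        if cache_file is not None and cache_file.exists():
            results[vid] = _load_outputs(cache_file)
            continue
        control, treat = _vector_params(row, varied, base_control, base_treat)
        outs = []
        for di, dose in enumerate(spec.doses):
            seed = int(
                np.random.SeedSequence([int(rng_seed), int(gi), di]).generate_state(1)[0]
                % (2**31)
            )
            outs.append(
                abm.simulate(
                    control,
                    treat=treat if dose > 0 else None,
                    C=dose,
                    t_grid=np.asarray(spec.t_grid),
                    n_reps=spec.n_reps,
                    dt=spec.dt,
                    rng_seed=seed,
                    n0=spec.n0,
                    init_phases=init_phases,
                )
            )
        results[vid] = outs
        if cache_file is not None:
            _save_outputs(cache_file, outs)
    return results


def _save_outputs(path: Path, outs: list[abm.ABMOutput]) -> None:
    blob = [
        {
            "times": o.times.tolist(),
            "counts": o.counts.tolist(),
            "dose": o.dose,
            "n0": o.n0,
            "seed": o.seed,
        }
        for o in outs
    ]
    path.write_text(json.dumps(blob))


def _load_outputs(path: Path) -> list[abm.ABMOutput]:
    blob = json.loads(path.read_text())
    return [
        abm.ABMOutput(
            times=np.asarray(o["times"], dtype=float),
            counts=np.asarray(o["counts"], dtype=np.int64),
            dose=o["dose"],
            n0=o["n0"],
            seed=o["seed"],
        )
        for o in blob
    ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating model and noise settings for a pseudo-experimental dataset."""

    generator: str = "surrogate"  # "surrogate" or "abm"
    sm_params: surrogate.SMControlParams | None = None
    control: abm.ABMControlParams | None = None
    treat: abm.ABMTreatmentParams | None = None
    doses: tuple[float, ...] = DEFAULT_DOSES
    times: tuple[float, ...] = DEFAULT_TIMES
    cv: float = 0.10
    n_replicates: int = 3
    n0: int = 100
    abm_reps: int = 6
    abm_dt: float = 0.25

    def __post_init__(self):
        if self.generator not in ("surrogate", "abm"):
            raise ValueError("generator must be 'surrogate' or 'abm'")
        if self.generator == "surrogate" and self.sm_params is None:
            raise ValueError("surrogate truth requires sm_params")
        if self.generator == "abm" and self.control is None:
            raise ValueError("abm truth requires control params")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")


def _truth_curves(truth: SyntheticTruth, rng_seed: int) -> dict[float, dict[str, np.ndarray]]:
    """Noise-free (ABM: replicate-averaged) observable curves per dose."""
    times = np.asarray(truth.times, dtype=float)
    curves: dict[float, dict[str, np.ndarray]] = {}
    for di, dose in enumerate(truth.doses):
        if truth.generator == "surrogate":
            p = truth.sm_params
            q = surrogate.stationary_split(p.lam, p.alpha)
            y0 = [q * truth.n0, (1 - q) * truth.n0, 0.0, 0.0]
            traj = surrogate.solve(p, y0, times, C=dose)
            curves[dose] = {
                "total_count": traj["N"].to_numpy(),
                "g2m_fraction": traj["g2m_fraction"].to_numpy(),
            }
        else:
            seed = int(
                np.random.SeedSequence([int(rng_seed), 7, di]).generate_state(1)[0] % (2**31)
            )
            out = abm.simulate(
                truth.control,
                treat=truth.treat if dose > 0 else None,
                C=dose,
                t_grid=times,
                n_reps=truth.abm_reps,
                dt=truth.abm_dt,
                rng_seed=seed,
                n0=truth.n0,
            )
            curves[dose] = {
                "total_count": out.total.mean(axis=0),
                "g2m_fraction": np.nanmean(out.g2m_fraction, axis=0),
            }
    return curves


def generate_dataset(truth: SyntheticTruth, rng_seed: int = 0) -> TimeSeriesDataset:
    """Pseudo-experimental dataset with the assay structure described above.

    Count arms are produced for every dose (including 0); G2/M-fraction
    arms only for nonzero doses.  Replicate values are the generating-model
    curve times mean-one lognormal noise at coefficient of variation
    ``truth.cv``; the arm mean and SD are taken across replicates.  With
    ``cv=0`` the means equal the generating model output exactly.
    """
    rng = np.random.default_rng(rng_seed)
    curves = _truth_curves(truth, rng_seed)
    times = np.asarray(truth.times, dtype=float)
    sigma = float(np.sqrt(np.log1p(truth.cv**2)))
    arms: list[Arm] = []

    def noisy(values: np.ndarray, clip01: bool) -> tuple[np.ndarray, np.ndarray]:
        if truth.cv == 0:
            reps = np.tile(values, (truth.n_replicates, 1))
        else:
            # mean-one multiplicative lognormal noise
            mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                 size=(truth.n_replicates, values.size))
            reps = values[None, :] * mult
        if clip01:
            reps = np.clip(reps, 0.0, 1.0)
        mean = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1) if truth.n_replicates > 1 else np.zeros_like(mean)
        return mean, sd

    for dose in truth.doses:
        mean, sd = noisy(curves[dose]["total_count"], clip01=False)
        arms.append(
            Arm(dose=dose, observable="total_count", times=times, mean=mean, sd=sd,
                n_replicates=truth.n_replicates)
        )
    for dose in truth.doses:
        if dose <= 0:
            continue  # control arm has no cycle-distribution data
        mean, sd = noisy(curves[dose]["g2m_fraction"], clip01=True)
        arms.append(
            Arm(dose=dose, observable="g2m_fraction", times=times, mean=mean, sd=sd,
                n_replicates=truth.n_replicates)
        )
    return TimeSeriesDataset(arms=tuple(arms), provenance="synthetic",
                             initial_count=float(truth.n0))
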