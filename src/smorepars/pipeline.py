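"""End-to-end SMoRe ParS studies: data -> surrogate -> ABM parameter space.

The study proceeds in the canonical order: fit the surrogate to the
(pseudo-)experimental data and profile its parameters (the data-informed
set S, as the confidence box Phi or the identifiable-combination paths
Psi); simulate the ABM over a factorial parameter grid; fit and profile the
surrogate against each vector's averaged output to obtain its confidence
hyperrectangle; accept each vector by rectangle-S intersection.  The
direct rejection-sampling baseline and the evaluation tables (level
proportions, RSS split, z-scores) are computed on the same artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import abm, acceptance, baseline, calibration, identifiability, synthdata
from .data import TimeSeriesDataset


@dataclass
class StudyResult:
    """All artifacts of one SMoRe ParS study."""

    data: TimeSeriesDataset
    grid: pd.DataFrame
    outputs: dict[str, list[abm.ABMOutput]]
    data_fit: calibration.CalibrationResults
    data_profiles: dict[str, identifiability.ProfileResult]
    grid_fits: dict[str, calibration.CalibrationResults]
    grid_profiles: dict[str, dict[str, identifiability.ProfileResult]]
    rectangles: dict[str, acceptance.HyperRectangle | None]
    S_phi: acceptance.DataInformedSet
    S_psi: acceptance.DataInformedSet
    records_phi: list[acceptance.AcceptanceRecord]
    records_psi: list[acceptance.AcceptanceRecord]
    mode: str
    rss_table: pd.DataFrame
    direct: baseline.DirectResult
    fit_failures: dict[str, str] = field(default_factory=dict)

    @property
    def records(self) -> list[acceptance.AcceptanceRecord]:
        return self.records_psi if self.mode == "psi" else self.records_phi

    @property
    def accepted(self) -> set[str]:
        return acceptance.accepted_ids(self.records)

    def level_proportions(self) -> pd.DataFrame:
        return acceptance.level_proportions(self.records)

    def rss_split(self) -> pd.DataFrame:
        return baseline.rss_split(self.rss_table, self.accepted)

    def zscores(self) -> pd.DataFrame:
        return baseline.zscores(self.outputs, self.data, accepted=self.accepted)

    def mean_accepted_trajectory(self, dose: float = 0.0) -> pd.DataFrame:
        """Mean and SD of the total-count trajectory over accepted vectors."""
        acc = sorted(self.accepted)
        if not acc:
            raise ValueError("accepted set is empty")
        times = self.outputs[acc[0]][0].times
        stacks = []
        for vid in acc:
            for out in self.outputs[vid]:
                if np.isclose(out.dose, dose):
                    stacks.append(out.total.mean(axis=0))
        arr = np.array(stacks)
        return pd.DataFrame(
            {"time_h": times, "mean": arr.mean(axis=0), "sd": arr.std(axis=0, ddof=1)}
        )


def profile_grid_fits(
    fits: Mapping[str, calibration.CalibrationResults],
    n_side: int = 12,
    level: float = 0.95,
    maxiter: int = 40,
) -> tuple[dict, dict]:
    """Profile every surrogate parameter of every per-vector fit.

    Returns ``(profiles, rectangles)``; vectors whose profiling fails map to
    ``None`` rectangles (marked indeterminate downstream).
    """
    profiles: dict[str, dict[str, identifiability.ProfileResult]] = {}
    rectangles: dict[str, acceptance.HyperRectangle | None] = {}
    for vid in sorted(fits):
        fit = fits[vid]
        try:
            profs = fit.profile_all(n_side=n_side, level=level, maxiter=maxiter)
            profiles[vid] = profs
            rectangles[vid] = acceptance.HyperRectangle.from_profiles(
                profs, fit.model.sm_param_names
            )
        except Exception as exc:  # pragma: no cover - per-vector guard
            warnings.warn(f"profiling failed for vector {vid}: {exc}")
            rectangles[vid] = None
    return profiles, rectangles


def run_study(
    data: TimeSeriesDataset,
    spec: synthdata.GridSpec,
    model: str = "control",
    base_control: abm.ABMControlParams | None = None,
    base_treat: abm.ABMTreatmentParams | None = None,
    mode: str = "psi",
    rng_seed: int = 0,
    n_starts_data: int = 20,
    n_starts_grid: int = 6,
    profile_side_points: int = 12,
    level: float = 0.95,
    cache_dir: str | Path | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> StudyResult:
    """Run a complete SMoRe ParS study against ``data`` over ``spec``'s grid.

    ``mode`` selects the default data-informed set (``"psi"``, the
    identifiable-combination paths, is the canonical choice); both Phi and
    Psi acceptance records are always computed so the superset property can
    be checked.
    """
    if mode not in ("phi", "psi"):
        raise ValueError("mode must be 'phi' or 'psi'")
    cache = Path(cache_dir) if cache_dir is not None else None

    # data-side calibration and profiling
    data_calib = calibration.SurrogateCalibration(data, model=model, bounds=bounds)
    data_fit = data_calib.fit(n_starts=n_starts_data, seed=int(rng_seed))
    data_profiles = data_fit.profile_all(n_side=profile_side_points, level=level)
    sm_names = data_calib.sm_param_names
    S_phi = acceptance.DataInformedSet.from_profiles(data_profiles, mode="phi", names=sm_names)
    S_psi = acceptance.DataInformedSet.from_profiles(data_profiles, mode="psi", names=sm_names)

    # ABM sweep over the grid
    grid = synthdata.make_grid(spec)
    outputs = synthdata.run_grid(
        spec,
        base_control=base_control,
        base_treat=base_treat,
        rng_seed=int(rng_seed) + 1,
        cache_dir=None if cache is None else cache / "abm",
    )
    datasets = {vid: abm.outputs_to_dataset(outs) for vid, outs in outputs.items()}

    # per-vector surrogate fits and confidence rectangles
    grid_fits, fit_failures = calibration.fit_grid(
        datasets,
        model=model,
        bounds=bounds,
        n_starts=n_starts_grid,
        rng_seed=int(rng_seed) + 2,
        cache_dir=None if cache is None else cache / "fits",
    )
    grid_profiles, rectangles = profile_grid_fits(
        grid_fits, n_side=profile_side_points, level=level
    )
    for vid in fit_failures:
        rectangles[vid] = None

    levels = synthdata.grid_levels(grid)
    records_phi = acceptance.run_acceptance(rectangles, S_phi, levels=levels)
    records_psi = acceptance.run_acceptance(rectangles, S_psi, levels=levels)

    # direct rejection-sampling baseline with k = |accepted|
    rss_table = baseline.abm_rss_table(outputs, data)
    records = records_psi if mode == "psi" else records_phi
    k = len(acceptance.accepted_ids(records))
    direct = baseline.direct_calibrate(rss_table, k=k)

    return StudyResult(
        data=data,
        grid=grid,
        outputs=outputs,
        data_fit=data_fit,
        data_profiles=data_profiles,
        grid_fits=grid_fits,
        grid_profiles=grid_profiles,
        rectangles=rectangles,
        S_phi=S_phi,
        S_psi=S_psi,
        records_phi=records_phi,
        records_psi=records_psi,
        mode=mode,
        rss_table=rss_table,
        direct=direct,
        fit_failures=fit_failures,
    )
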