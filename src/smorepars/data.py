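"""Multi-arm time-series containers.

The experimental design this mirrors is a cell growth-inhibition assay: total
viable cell counts (normalized to 100 cells at t=0) under several constant
drug doses, plus flow-cytometry G2/M fractions for the treated arms.  Each
(dose, observable) pair is one *arm*: a short time series with a replicate
mean and standard deviation at every time point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Observables an arm may carry.  ``total_count`` and ``g2m_fraction`` are the
#: assay-style observables; the compartment counts are available when the data
#: source is a simulation that reports them (used when fitting surrogate
#: parameters to simulated output).
OBSERVABLES = ("total_count", "g2m_fraction", "g1s_count", "g2m_count")

FRACTION_OBSERVABLES = ("g2m_fraction",)

_CSV_COLUMNS = ["dose_uM", "observable", "time_h", "mean", "sd", "n_replicates"]


@dataclass(frozen=True)
class Arm:
    """One (dose, observable) time course with replicate mean and SD."""

    dose: float
    observable: str
    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: int | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        mean = np.asarray(self.mean, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "mean", mean)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        if times.size == 0:
            raise ValueError("arm must contain at least one time point")
        if np.any(np.diff(times) <= 0):
            raise ValueError("arm times must be strictly increasing")
        if mean.shape != times.shape:
            raise ValueError("mean and times must have the same shape")
        if self.sd is not None:
            if self.sd.shape != times.shape:
                raise ValueError("sd and times must have the same shape")
            if np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.observable in FRACTION_OBSERVABLES:
            if np.any((mean < 0) | (mean > 1)):
                raise ValueError("fraction observables must lie in [0, 1]")

    @property
    def key(self) -> tuple[float, str]:
        return (self.dose, self.observable)


@dataclass(frozen=True)
class TimeSeriesDataset:
    """A collection of arms plus a provenance tag.

    ``provenance`` records where the numbers came from: ``"experimental"``
    (measured data), ``"abm"`` (simulated lattice-model output), or
    ``"synthetic"`` (generator output emulating the experimental structure).
    """

    arms: tuple[Arm, ...]
    provenance: str = "synthetic"
    initial_count: float = 100.0

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(self.arms))
        if not self.arms:
            raise ValueError("dataset must contain at least one arm")
        if self.provenance not in ("experimental", "abm", "synthetic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        keys = [a.key for a in self.arms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (dose, observable) arm")

    def __iter__(self) -> Iterable[Arm]:
        return iter(self.arms)

    def __len__(self) -> int:
        return len(self.arms)

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted({a.dose for a in self.arms}))

    def arm(self, dose: float, observable: str) -> Arm:
        for a in self.arms:
            if a.observable == observable and np.isclose(a.dose, dose):
                return a
        raise KeyError(f"no arm (dose={dose}, observable={observable!r})")

    def subset(self, observables: Sequence[str]) -> "TimeSeriesDataset":
        arms = tuple(a for a in self.arms if a.observable in observables)
        if not arms:
            raise ValueError("subset would be empty")
        return replace(self, arms=arms)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            sd = a.sd if a.sd is not None else np.full_like(a.times, np.nan)
            for t, m, s in zip(a.times, a.mean, sd):
                rows.append((a.dose, a.observable, t, m, s, a.n_replicates))
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, provenance: str = "experimental", initial_count: float = 100.0
    ) -> "TimeSeriesDataset":
        arms = []
        for (dose, obs), g in frame.groupby(["dose_uM", "observable"], sort=True):
            g = g.sort_values("time_h")
            sd = g["sd"].to_numpy(dtype=float)
            if np.all(np.isnan(sd)):
                sd = None
            nrep = g["n_replicates"].iloc[0]
            nrep = None if pd.isna(nrep) else int(nrep)
            arms.append(
                Arm(
                    dose=float(dose),
                    observable=str(obs),
                    times=g["time_h"].to_numpy(dtype=float),
                    mean=g["mean"].to_numpy(dtype=float),
                    sd=sd,
                    n_replicates=nrep,
                )
            )
        return cls(arms=tuple(arms), provenance=provenance, initial_count=initial_count)

    @classmethod
    def read_csv(
        cls, path: str | Path, provenance: str = "experimental", initial_count: float = 100.0
    ) -> "TimeSeriesDataset":
        return cls.from_frame(pd.read_csv(path), provenance=provenance, initial_count=initial_count)
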