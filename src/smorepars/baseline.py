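"""Direct rejection-sampling baseline and shared evaluation statistics.

The direct method ranks ABM parameter vectors by the weighted RSS of their
mean simulated trajectories against the data (the same objective used for
surrogate calibration) and accepts the ``k`` lowest, with ``k`` set to the
SMoRe ParS accepted count when comparing the two methods.  The z-score and
RSS-split tables quantify, per time point and per arm, how accepted and
rejected vectors differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abm import ABMOutput
from .calibration import AlignmentError, weighted_rss
from .data import TimeSeriesDataset


def _mean_predictions(
    outputs: Sequence[ABMOutput], data: TimeSeriesDataset
) -> dict[tuple[float, str], np.ndarray]:
    """Mean-trajectory values of each data arm's observable at the data times."""
    by_dose = {out.dose: out for out in outputs}
    preds = {}
    for arm in data:
        if arm.dose not in by_dose:
            raise AlignmentError(f"no simulated output at dose {arm.dose}")
        out = by_dose[arm.dose]
        idx = _time_index(out.times, arm.times)
        vals = np.nanmean(out.observable(arm.observable), axis=0)
        preds[arm.key] = vals[idx]
    return preds


def _time_index(sim_times: np.ndarray, data_times: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(sim_times, data_times)
    idx = np.clip(idx, 0, sim_times.size - 1)
    if not np.allclose(sim_times[idx], data_times, rtol=0, atol=1e-6):
        raise AlignmentError("simulated grid does not cover the data time points")
    return idx


def abm_rss_table(
    outputs: Mapping[str, Sequence[ABMOutput]],
    data: TimeSeriesDataset,
    floor_frac: float = 0.05,
    arm_multipliers: Mapping[tuple[float, str], float] | None = None,
) -> pd.DataFrame:
    """Weighted RSS of every vector's mean trajectory vs the data.

    One row per vector with the total and one ``rss|<dose>|<observable>``
    column per arm; per-arm contributions sum to the total.
    """
    rows = []
    for vid in sorted(outputs):
        preds = _mean_predictions(outputs[vid], data)
        total, per_arm = weighted_rss(preds, data, floor_frac, arm_multipliers)
        row = {"vector_id": vid, "rss": total}
        for (dose, obs), v in per_arm.items():
            row[f"rss|{dose:g}|{obs}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DirectResult:
    """Rejection-sampling outcome: ranked RSS table and accepted flags."""

    table: pd.DataFrame  # vector_id, rss, rank, accepted
    k: int
    had_ties: bool

    @property
    def accepted_ids(self) -> set[str]:
        return set(self.table.loc[self.table["accepted"], "vector_id"])


def direct_calibrate(
    rss_table: pd.DataFrame,
    k: int,
) -> DirectResult:
    """Accept the ``k`` lowest-RSS vectors (ties broken by vector id).

    ``rss_table`` is the frame from :func:`abm_rss_table` (or any frame with
    ``vector_id`` and ``rss`` columns).
    """
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k > len(rss_table):
        raise ValueError("k exceeds the number of vectors")
    tab = rss_table.sort_values(["rss", "vector_id"], kind="mergesort").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["accepted"] = tab["rank"] <= k
    had_ties = False
    if 0 < k < len(tab):
        had_ties = bool(np.isclose(tab["rss"].iloc[k - 1], tab["rss"].iloc[k]))
    return DirectResult(table=tab, k=k, had_ties=had_ties)


def zscores(
    outputs: Mapping[str, Sequence[ABMOutput]],
    data: TimeSeriesDataset,
    accepted: set[str] | None = None,
) -> pd.DataFrame:
    """Z-scores of simulated values against the data mean and SD.

    ``z = (simulated - data_mean) / data_SD`` per (vector, arm, time), both
    per replicate (``replicate`` = 0..n-1) and for the mean trajectory
    (``replicate`` = ``"mean"``).  Points with zero or missing data SD are
    scored as missing with a warning flag column.
    """
    rows = []
    for vid in sorted(outputs):
        by_dose = {out.dose: out for out in outputs[vid]}
        for arm in data:
            if arm.dose not in by_dose:
                raise AlignmentError(f"no simulated output at dose {arm.dose}")
            out = by_dose[arm.dose]
            idx = _time_index(out.times, arm.times)
            sd = arm.sd
            vals = out.observable(arm.observable)[:, idx]
            mean_vals = np.nanmean(vals, axis=0)
            for ti, t in enumerate(arm.times):
                s = np.nan if sd is None else sd[ti]
                bad = (s is None) or not np.isfinite(s) or s <= 0
                for r in range(vals.shape[0]):
                    z = np.nan if bad else (vals[r, ti] - arm.mean[ti]) / s
                    rows.append((vid, arm.dose, arm.observable, t, str(r), z, bad))
                z = np.nan if bad else (mean_vals[ti] - arm.mean[ti]) / s
                rows.append((vid, arm.dose, arm.observable, t, "mean", z, bad))
    df = pd.DataFrame(
        rows,
        columns=["vector_id", "dose_uM", "observable", "time_h", "replicate", "z", "missing_sd"],
    )
    if accepted is not None:
        df["accepted"] = df["vector_id"].isin(accepted)
    return df


def rss_split(
    rss_table: pd.DataFrame,
    accepted: set[str],
) -> pd.DataFrame:
    """Accepted-vs-rejected summary of RSS, total and per arm.

    Returns median, quartiles and tail (95th percentile) per group for the
    total RSS and each per-arm contribution column.
    """
    tab = rss_table.copy()
    tab["group"] = np.where(tab["vector_id"].isin(accepted), "accepted", "rejected")
    value_cols = ["rss"] + [c for c in tab.columns if c.startswith("rss|")]
    rows = []
    for group, g in tab.groupby("group"):
        for col in value_cols:
            v = g[col].to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "component": col,
                    "n": v.size,
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                    "p95": float(np.percentile(v, 95)),
                }
            )
    return pd.DataFrame(rows)
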