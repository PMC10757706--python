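"""The acceptance step: intersecting confidence boxes with data-informed sets.

For every ABM parameter vector, the 95% profile-likelihood confidence
intervals of the surrogate parameters (fitted to that vector's simulated
output) define an axis-aligned hyperrectangle in surrogate-parameter space;
endpoints flagged unbounded become infinite faces.  The experimental data
define a set S in the same space, in one of two ways:

* ``Phi`` - the Cartesian product of the data-derived confidence intervals
  (a box), or
* ``Psi`` - the union of the data-derived practically identifiable
  combination paths (polylines), a subset of Phi by projection.

An ABM vector is accepted iff its hyperrectangle has nonempty intersection
with S (closed sets: boundary contact counts).  Because every Psi vertex
projects into each data confidence interval, acceptance under Psi implies
acceptance under Phi - the superset property asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .identifiability import IdentifiableCombination, ProfileResult, extract_combinations


@dataclass(frozen=True)
class HyperRectangle:
    """Axis-aligned closed box; faces may be infinite (unbounded CIs)."""

    names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValueError("lo/hi must have one entry per dimension")
        if np.any(lo > hi):
            raise ValueError("lo must be <= hi in every dimension")

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, ProfileResult],
        names: Sequence[str],
        param_bounds: Mapping[str, tuple[float, float]] | None = None,
    ) -> "HyperRectangle":
        """Per-parameter interval = its profile CI; unbounded flags map to
        infinite faces (lower flag to the parameter's natural floor: 0 for
        rates, -inf otherwise; upper flag to +inf)."""
        lo, hi = [], []
        for n in names:
            if n not in profiles:
                raise KeyError(f"missing profile for parameter {n!r}")
            p = profiles[n]
            lo_v, hi_v = p.ci
            if p.lower_unbounded:
                floor = 0.0
                if param_bounds is not None and param_bounds[n][0] < 0:
                    floor = -np.inf
                lo_v = floor
            if p.upper_unbounded:
                hi_v = np.inf
            lo.append(lo_v)
            hi.append(hi_v)
        return cls(names=tuple(names), lo=np.array(lo), hi=np.array(hi))

    def contains(self, point: np.ndarray) -> bool:
        point = np.asarray(point, dtype=float)
        return bool(np.all(point >= self.lo) and np.all(point <= self.hi))


def intersects_box(r1: HyperRectangle, r2: HyperRectangle) -> bool:
    """True iff the closed boxes overlap in every dimension (ties count)."""
    if r1.names != r2.names:
        raise ValueError("dimension/name mismatch between rectangles")
    return bool(np.all(r1.lo <= r2.hi) and np.all(r2.lo <= r1.hi))


def _segment_hits_box(p: np.ndarray, q: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
    """Exact slab test: does the closed segment p->q meet the closed box?"""
    t0, t1 = 0.0, 1.0
    for d in range(p.size):
        dp = q[d] - p[d]
        if dp == 0.0:
            if p[d] < lo[d] or p[d] > hi[d]:
                return False
            continue
        ta = (lo[d] - p[d]) / dp
        tb = (hi[d] - p[d]) / dp
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return False
    return True


@dataclass
class DataInformedSet:
    """The experimental data-informed set S (mode ``"phi"`` or ``"psi"``).

    Phi is a single box; Psi is a list of polylines living inside that box
    (projection property).  Both carry the same parameter-name axes as the
    per-vector rectangles they are intersected with.
    """

    mode: str
    names: tuple[str, ...]
    box: HyperRectangle
    paths: list[np.ndarray] | None = None

    def __post_init__(self):
        if self.mode not in ("phi", "psi"):
            raise ValueError("mode must be 'phi' or 'psi'")
        if self.mode == "psi":
            if not self.paths or all(p.shape[0] == 0 for p in self.paths):
                raise ValueError("psi mode requires at least one nonempty path")

    @classmethod
    def from_profiles(
        cls,
        profiles: Mapping[str, ProfileResult],
        mode: str = "psi",
        names: Sequence[str] | None = None,
    ) -> "DataInformedSet":
        names = tuple(names) if names is not None else tuple(profiles)
        box = HyperRectangle.from_profiles(profiles, names)
        paths = None
        if mode == "psi":
            comb = extract_combinations([profiles[n] for n in names], sm_names=names)
            paths = comb.polylines
        return cls(mode=mode, names=names, box=box, paths=paths)

    @property
    def dimension(self) -> int:
        return len(self.names)


def intersects_path(rect: HyperRectangle, psi: DataInformedSet) -> bool:
    """True iff any Psi polyline meets the closed rectangle.

    Vertices are tested directly; each polyline segment is additionally
    checked with an exact slab segment-box test so a path cannot tunnel
    through a thin box between two outside vertices.
    """
    if psi.mode != "psi":
        raise ValueError("intersects_path requires a Psi-mode set")
    if rect.names != psi.names:
        raise ValueError("dimension/name mismatch")
    for poly in psi.paths:
        if poly.shape[0] == 0:
            continue
        inside = (poly >= rect.lo) & (poly <= rect.hi)
        if np.any(np.all(inside, axis=1)):
            return True
        for k in range(poly.shape[0] - 1):
            if _segment_hits_box(poly[k], poly[k + 1], rect.lo, rect.hi):
                return True
    return False


def intersects(rect: HyperRectangle, S: DataInformedSet) -> bool:
    if S.mode == "phi":
        return intersects_box(rect, S.box)
    return intersects_path(rect, S)


@dataclass(frozen=True)
class AcceptanceRecord:
    """Outcome of the acceptance test for one ABM parameter vector."""

    vector_id: str
    levels: dict[str, str]
    rectangle: HyperRectangle | None
    accepted: bool
    mode: str
    indeterminate: bool = False


def run_acceptance(
    rectangles: Mapping[str, HyperRectangle | None],
    S: DataInformedSet,
    levels: Mapping[str, Mapping[str, str]] | None = None,
    mode: str | None = None,
) -> list[AcceptanceRecord]:
    """Accept/reject every ABM vector by rectangle-S intersection.

    ``rectangles`` may map a vector to ``None`` when its profiles failed;
    such vectors are marked indeterminate (reported, never silently
    rejected).  ``mode`` defaults to the mode of ``S``.
    """
    mode = mode or S.mode
    records = []
    for vid in sorted(rectangles):
        rect = rectangles[vid]
        lv = dict(levels[vid]) if levels is not None else {}
        if rect is None:
            records.append(
                AcceptanceRecord(vid, lv, None, accepted=False, mode=mode, indeterminate=True)
            )
            continue
        records.append(
            AcceptanceRecord(vid, lv, rect, accepted=intersects(rect, S), mode=mode)
        )
    return records


def accepted_ids(records: Sequence[AcceptanceRecord]) -> set[str]:
    return {r.vector_id for r in records if r.accepted}


def level_proportions(records: Sequence[AcceptanceRecord]) -> pd.DataFrame:
    """Per-(parameter, level) share of accepted vectors.

    Within each parameter the proportions sum to 1 over levels of the
    accepted set.  An empty accepted set yields an empty frame with an
    ``empty`` attribute flag.
    """
    acc = [r for r in records if r.accepted]
    rows = []
    if acc:
        params = sorted({p for r in acc for p in r.levels})
        for p in params:
            counts: dict[str, int] = {}
            for r in acc:
                lab = r.levels.get(p)
                if lab is not None:
                    counts[lab] = counts.get(lab, 0) + 1
            total = sum(counts.values())
            for lab, c in sorted(counts.items()):
                rows.append({"parameter": p, "level": lab, "count": c, "proportion": c / total})
    df = pd.DataFrame(rows, columns=["parameter", "level", "count", "proportion"])
    df.attrs["empty_accepted_set"] = not acc
    return df


def records_to_frame(records: Sequence[AcceptanceRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"vector_id": r.vector_id, "accepted": r.accepted, "mode": r.mode,
               "indeterminate": r.indeterminate}
        for p, lab in r.levels.items():
            row[f"level_{p}"] = lab
        rows.append(row)
    return pd.DataFrame(rows)
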