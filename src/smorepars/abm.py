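"""2D on-lattice birth-death-migration ABM with cell-cycle progression.

Each agent is a cell on a square lattice, progressing through the cycle
phases G1 -> S -> G2 -> M with per-phase exponential transition rates.  On
the M -> G1 transition the cell divides into a uniformly chosen open von
Neumann neighbor, unless contact inhibition blocks mitosis (fewer than
``T_con`` open neighbors), in which case it re-enters G1 alone.  Under
chemotherapy at constant concentration ``C``, an otherwise-successful
G1->S or G2->M transition instead arrests the cell with probability
``r_i * C^a / (gamma1^a + C^a)``; arrested cells neither cycle nor move and
die at rate ``delta_p * C^b / (gamma2^b + C^b)``, being removed after all
other updates in the step.  Non-advancing cells migrate at rate ``s`` to a
uniformly chosen open neighbor.

Continuous rates are converted to per-step probabilities via
``1 - exp(-rate*dt)`` (exact for exponential waiting times).  Agents update
in a fresh uniform random order each step; moves and divisions take effect
immediately.  The lattice has closed boundaries (no wraparound).

The per-agent loop is compiled with numba; replicate seeds are spawned from
a single ``numpy.random.SeedSequence`` so identical seeds give bitwise-
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .data import Arm, TimeSeriesDataset

PHASES = ("G1", "S", "G2", "M")
COUNT_COLUMNS = ("n_G1", "n_S", "n_G2", "n_M", "a_G1S", "a_G2M")


# ----------------------------------------------------------------- parameters


@dataclass(frozen=True)
class ABMControlParams:
    """Input parameters of the untreated simulator (rates per hour)."""

    K_A: int = 2500        # carrying capacity (lattice sites)
    T_con: int = 2         # open von Neumann neighbors required for mitosis
    s: float = 1.0         # migration rate
    rho_G1S: float = 1 / 11.0
    rho_SG2: float = 1 / 8.0
    rho_G2M: float = 1 / 4.0
    rho_MG1: float = 1.0

    def __post_init__(self):
        if int(self.K_A) < 1:
            raise ValueError("K_A must be a positive integer")
        if self.T_con not in (0, 1, 2, 3, 4):
            raise ValueError("T_con must be an integer in [0, 4]")
        rates = (self.s, self.rho_G1S, self.rho_SG2, self.rho_G2M, self.rho_MG1)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be nonnegative")

    @property
    def rhos(self) -> np.ndarray:
        return np.array([self.rho_G1S, self.rho_SG2, self.rho_G2M, self.rho_MG1])

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ABMTreatmentParams:
    """Drug-response parameters: checkpoint arrest and apoptosis Hill terms."""

    r_G1: float = 0.5      # max arrest probability at the G1->S checkpoint
    r_G2: float = 0.5      # max arrest probability at the G2->M checkpoint
    gamma1: float = 2.0    # EC50 of arrest, uM
    delta_p: float = 0.03  # max apoptosis rate of arrested cells, /h
    gamma2: float = 2.0    # EC50 of apoptosis, uM
    a: float = 1.0         # arrest Hill exponent (held fixed)
    b: float = 1.0         # apoptosis Hill exponent (held fixed)

    def __post_init__(self):
        if not (0 <= self.r_G1 <= 1 and 0 <= self.r_G2 <= 1):
            raise ValueError("r_G1, r_G2 must lie in [0, 1]")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("gamma1, gamma2 must be positive")
        if self.delta_p < 0:
            raise ValueError("delta_p must be nonnegative")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# --------------------------------------------------------------- scalar rules


def microenvironment_dims(K_A: int) -> tuple[int, int]:
    """Lattice dimensions for carrying capacity ``K_A``.

    ``l = ceil(sqrt(K_A))`` and ``w = ceil(K_A / l)``, so ``l*w >= K_A``.
    """
    if int(K_A) < 1:
        raise ValueError("K_A must be a positive integer")
    K_A = int(K_A)
    l = math.isqrt(K_A)
    if l * l < K_A:
        l += 1
    w = -(-K_A // l)
    return l, w


def arrest_probability(C: float, r: float, gamma1: float, a: float = 1.0) -> float:
    """Dose-dependent checkpoint arrest probability ``r * C^a/(gamma1^a + C^a)``."""
    if gamma1 <= 0:
        raise ValueError("gamma1 must be positive")
    if C < 0:
        raise ValueError("concentration must be nonnegative")
    if not 0 <= r <= 1:
        raise ValueError("r must lie in [0, 1]")
    if C == 0:
        return 0.0
    ca = C**a
    return r * ca / (gamma1**a + ca)


def apoptosis_rate(C: float, delta_p: float, gamma2: float, b: float = 1.0) -> float:
    """Dose-dependent apoptosis rate ``delta_p * C^b/(gamma2^b + C^b)`` (per hour)."""
    if gamma2 <= 0:
        raise ValueError("gamma2 must be positive")
    if C < 0 or delta_p < 0:
        raise ValueError("C and delta_p must be nonnegative")
    if C == 0:
        return 0.0
    cb = C**b
    return delta_p * cb / (gamma2**b + cb)


def rate_to_step_probability(rate: float, dt: float) -> float:
    """Per-step event probability ``1 - exp(-rate*dt)`` for a rate per hour."""
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return -math.expm1(-rate * dt)


def stationary_phase_distribution(rhos: Sequence[float]) -> np.ndarray:
    """Cycle-phase occupancy proportional to mean dwell time ``1/rho`` per phase."""
    rhos = np.asarray(rhos, dtype=float)
    if np.any(rhos <= 0):
        # degenerate cycle: place everything in the first non-advancing phase
        p = np.zeros(4)
        p[int(np.argmin(rhos))] = 1.0
        return p
    inv = 1.0 / rhos
    return inv / inv.sum()


# ------------------------------------------------------------- lattice state


@dataclass
class LatticeState:
    """Mutable lattice configuration (agent-slot arrays plus occupancy grid)."""

    l: int
    w: int
    grid: np.ndarray      # (l, w) int32: slot index or -1 for open
    phase: np.ndarray     # (cap,) int8: 0..3 = G1,S,G2,M
    arrested: np.ndarray  # (cap,) int8: 0 cycling, 1 arrested G1/S, 2 arrested G2/M
    alive: np.ndarray     # (cap,) bool
    ax: np.ndarray        # (cap,) int32 row
    ay: np.ndarray        # (cap,) int32 column
    free: np.ndarray      # (cap,) int32 recycled-slot stack
    free_top: int
    hi: int               # one past the highest slot ever used
    clock: float = 0.0

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self.hi].sum())

    def counts(self) -> np.ndarray:
        """Counts ``(n_G1, n_S, n_G2, n_M, a_G1S, a_G2M)`` of alive agents."""
        out = np.zeros(6, dtype=np.int64)
        _count_kernel(self.phase, self.arrested, self.alive, self.hi, out)
        return out

    def check(self) -> None:
        """Assert structural invariants (unique coordinates, grid consistency)."""
        occupied = np.argwhere(self.grid >= 0)
        assert occupied.shape[0] == self.n_alive
        for x, y in occupied:
            i = self.grid[x, y]
            assert self.alive[i] and self.ax[i] == x and self.ay[i] == y


def seed_lattice(
    control: ABMControlParams,
    n0: int,
    rng_seed: int,
    init_phases: str = "stationary",
) -> LatticeState:
    """Seed ``n0`` agents at distinct uniformly sampled sites.

    ``init_phases`` is ``"stationary"`` (each agent's phase drawn from the
    dwell-time-weighted cycle distribution, avoiding synchronization
    transients) or ``"g1"`` (all agents start in G1).
    """
    l, w = microenvironment_dims(control.K_A)
    if n0 < 0 or n0 > l * w:
        raise ValueError(f"n0 must lie in [0, {l * w}]")
    if init_phases == "stationary":
        pdist = stationary_phase_distribution(control.rhos)
    elif init_phases == "g1":
        pdist = np.array([1.0, 0.0, 0.0, 0.0])
    else:
        raise ValueError("init_phases must be 'stationary' or 'g1'")
    cap = l * w
    state = LatticeState(
        l=l,
        w=w,
        grid=np.full((l, w), -1, dtype=np.int32),
        phase=np.zeros(cap, dtype=np.int8),
        arrested=np.zeros(cap, dtype=np.int8),
        alive=np.zeros(cap, dtype=np.bool_),
        ax=np.zeros(cap, dtype=np.int32),
        ay=np.zeros(cap, dtype=np.int32),
        free=np.zeros(cap, dtype=np.int32),
        free_top=0,
        hi=n0,
        clock=0.0,
    )
    _seed_rng(int(rng_seed) & 0x7FFFFFFF)
    _seed_kernel(
        state.grid, state.phase, state.alive, state.ax, state.ay, n0, np.cumsum(pdist)
    )
    return state


def step(
    state: LatticeState,
    control: ABMControlParams,
    treat: ABMTreatmentParams | None = None,
    C: float = 0.0,
    dt: float = 0.25,
    seed: int | None = None,
) -> LatticeState:
    """Advance the lattice by one time step of ``dt`` hours (in place).

    If ``seed`` is given the random stream is reseeded first; otherwise the
    stream continues from the previous kernel call.
    """
    if C < 0:
        raise ValueError("concentration must be nonnegative")
    if seed is not None:
        _seed_rng(int(seed) & 0x7FFFFFFF)
    p_adv = np.array([rate_to_step_probability(r, dt) for r in control.rhos])
    p_move = rate_to_step_probability(control.s, dt)
    if treat is not None and C > 0:
        p_arr_g1 = arrest_probability(C, treat.r_G1, treat.gamma1, treat.a)
        p_arr_g2 = arrest_probability(C, treat.r_G2, treat.gamma1, treat.a)
        p_die = rate_to_step_probability(apoptosis_rate(C, treat.delta_p, treat.gamma2, treat.b), dt)
    else:
        p_arr_g1 = p_arr_g2 = p_die = 0.0
    state.free_top, state.hi = _step_kernel(
        state.grid,
        state.phase,
        state.arrested,
        state.alive,
        state.ax,
        state.ay,
        state.free,
        state.free_top,
        state.hi,
        p_adv,
        p_arr_g1,
        p_arr_g2,
        p_move,
        p_die,
        int(control.T_con),
    )
    state.clock += dt
    return state


# ------------------------------------------------------------ jitted kernels


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - jitted
    np.random.seed(seed)


@njit(cache=True)
def _count_kernel(phase, arrested, alive, hi, out):  # pragma: no cover - jitted
    for i in range(hi):
        if not alive[i]:
            continue
        if arrested[i] == 1:
            out[4] += 1
        elif arrested[i] == 2:
            out[5] += 1
        else:
            out[phase[i]] += 1


@njit(cache=True)
def _seed_kernel(grid, phase, alive, ax, ay, n0, phase_cdf):  # pragma: no cover - jitted
    l, w = grid.shape
    cap = l * w
    sites = np.arange(cap).astype(np.int32)
    for i in range(n0):
        j = i + np.random.randint(0, cap - i)
        tmp = sites[i]
        sites[i] = sites[j]
        sites[j] = tmp
        s = sites[i]
        x = s // w
        y = s % w
        grid[x, y] = i
        ax[i] = x
        ay[i] = y
        alive[i] = True
        u = np.random.random()
        ph = 0
        while ph < 3 and u > phase_cdf[ph]:
            ph += 1
        phase[i] = ph


@njit(cache=True, inline="always")
def _open_neighbors(grid, x, y, nbx, nby):  # pragma: no cover - jitted
    l, w = grid.shape
    n = 0
    if x > 0 and grid[x - 1, y] < 0:
        nbx[n] = x - 1
        nby[n] = y
        n += 1
    if x < l - 1 and grid[x + 1, y] < 0:
        nbx[n] = x + 1
        nby[n] = y
        n += 1
    if y > 0 and grid[x, y - 1] < 0:
        nbx[n] = x
        nby[n] = y - 1
        n += 1
    if y < w - 1 and grid[x, y + 1] < 0:
        nbx[n] = x
        nby[n] = y + 1
        n += 1
    return n


@njit(cache=True)
def _step_kernel(
    grid,
    phase,
    arrested,
    alive,
    ax,
    ay,
    free,
    free_top,
    hi,
    p_adv,
    p_arr_g1,
    p_arr_g2,
    p_move,
    p_die,
    t_con,
):  # pragma: no cover - jitted
    cap = grid.shape[0] * grid.shape[1]
    order = np.empty(cap, np.int32)
    n_ord = 0
    for i in range(hi):
        if alive[i]:
            order[n_ord] = i
            n_ord += 1
    # fresh uniform random permutation of update order each step
    for i in range(n_ord - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = order[i]
        order[i] = order[j]
        order[j] = tmp
    dead = np.empty(cap, np.int32)
    n_dead = 0
    nbx = np.empty(4, np.int32)
    nby = np.empty(4, np.int32)
    for oi in range(n_ord):
        i = order[oi]
        if arrested[i] != 0:
            # absorbing up to death: apoptosis draw only
            if p_die > 0.0 and np.random.random() < p_die:
                dead[n_dead] = i
                n_dead += 1
            continue
        ph = phase[i]
        if np.random.random() < p_adv[ph]:
            if ph == 0:  # G1 -> S checkpoint
                if p_arr_g1 > 0.0 and np.random.random() < p_arr_g1:
                    arrested[i] = 1
                else:
                    phase[i] = 1
            elif ph == 1:  # S -> G2
                phase[i] = 2
            elif ph == 2:  # G2 -> M checkpoint
                if p_arr_g2 > 0.0 and np.random.random() < p_arr_g2:
                    arrested[i] = 2
                else:
                    phase[i] = 3
            else:  # M -> G1, possibly with mitosis
                n_open = _open_neighbors(grid, ax[i], ay[i], nbx, nby)
                phase[i] = 0
                if n_open >= t_con and n_open >= 1:
                    k = np.random.randint(0, n_open)
                    if free_top > 0:
                        free_top -= 1
                        j = free[free_top]
                    else:
                        j = hi
                        hi += 1
                    grid[nbx[k], nby[k]] = j
                    ax[j] = nbx[k]
                    ay[j] = nby[k]
                    phase[j] = 0
                    arrested[j] = 0
                    alive[j] = True
        elif p_move > 0.0 and np.random.random() < p_move:
            n_open = _open_neighbors(grid, ax[i], ay[i], nbx, nby)
            if n_open > 0:
                k = np.random.randint(0, n_open)
                grid[ax[i], ay[i]] = -1
                ax[i] = nbx[k]
                ay[i] = nby[k]
                grid[ax[i], ay[i]] = i
    # deaths are removed after all other updates
    for di in range(n_dead):
        i = dead[di]
        alive[i] = False
        grid[ax[i], ay[i]] = -1
        free[free_top] = i
        free_top += 1
    return free_top, hi


@njit(cache=True)
def _run_kernel(
    l,
    w,
    n0,
    seed,
    record_at,
    p_adv,
    p_arr_g1,
    p_arr_g2,
    p_move,
    p_die,
    t_con,
    phase_cdf,
):  # pragma: no cover - jitted
    np.random.seed(seed)
    cap = l * w
    grid = np.full((l, w), -1, np.int32)
    phase = np.zeros(cap, np.int8)
    arrested = np.zeros(cap, np.int8)
    alive = np.zeros(cap, np.bool_)
    ax = np.zeros(cap, np.int32)
    ay = np.zeros(cap, np.int32)
    free = np.zeros(cap, np.int32)
    _seed_kernel(grid, phase, alive, ax, ay, n0, phase_cdf)
    free_top = 0
    hi = n0
    n_rec = record_at.shape[0]
    out = np.zeros((n_rec, 6), np.int64)
    rec_i = 0
    while rec_i < n_rec and record_at[rec_i] == 0:
        _count_kernel(phase, arrested, alive, hi, out[rec_i])
        rec_i += 1
    n_steps = record_at[n_rec - 1]
    for step_idx in range(1, n_steps + 1):
        free_top, hi = _step_kernel(
            grid, phase, arrested, alive, ax, ay, free, free_top, hi,
            p_adv, p_arr_g1, p_arr_g2, p_move, p_die, t_con,
        )
        while rec_i < n_rec and record_at[rec_i] == step_idx:
            _count_kernel(phase, arrested, alive, hi, out[rec_i])
            rec_i += 1
    return out


# ------------------------------------------------------------------- outputs


@dataclass(frozen=True)
class ABMOutput:
    """Replicate phase/arrest counts recorded on a time grid at one dose."""

    times: np.ndarray   # (n_times,) hours
    counts: np.ndarray  # (n_reps, n_times, 6) in COUNT_COLUMNS order
    dose: float
    n0: int
    seed: int

    @property
    def n_reps(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> np.ndarray:
        """Alive count per (replicate, time)."""
        return self.counts.sum(axis=2)

    @property
    def g1s_count(self) -> np.ndarray:
        """Cycling G1+S plus arrested-in-G1/S, per (replicate, time)."""
        return self.counts[:, :, 0] + self.counts[:, :, 1] + self.counts[:, :, 4]

    @property
    def g2m_count(self) -> np.ndarray:
        """Cycling G2+M plus arrested-in-G2/M, per (replicate, time)."""
        return self.counts[:, :, 2] + self.counts[:, :, 3] + self.counts[:, :, 5]

    @property
    def g2m_fraction(self) -> np.ndarray:
        total = self.total
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(total > 0, self.g2m_count / total, np.nan)

    def observable(self, name: str) -> np.ndarray:
        if name == "total_count":
            return self.total.astype(float)
        if name == "g1s_count":
            return self.g1s_count.astype(float)
        if name == "g2m_count":
            return self.g2m_count.astype(float)
        if name == "g2m_fraction":
            return self.g2m_fraction
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: replicate, time_h, dose_uM, per-bucket counts, total."""
        rows = []
        for r in range(self.n_reps):
            for ti, t in enumerate(self.times):
                rows.append(
                    (r, t, self.dose, *self.counts[r, ti], int(self.counts[r, ti].sum()))
                )
        return pd.DataFrame(
            rows, columns=["replicate", "time_h", "dose_uM", *COUNT_COLUMNS, "total"]
        )

    def arms(self, observables: Sequence[str], drop_t0: bool = True) -> list[Arm]:
        """Replicate mean/SD arms for the requested observables."""
        keep = self.times > 0 if drop_t0 else np.ones_like(self.times, bool)
        out = []
        for obs in observables:
            vals = self.observable(obs)[:, keep]
            out.append(
                Arm(
                    dose=self.dose,
                    observable=obs,
                    times=self.times[keep],
                    mean=vals.mean(axis=0),
                    sd=vals.std(axis=0, ddof=1) if self.n_reps > 1 else None,
                    n_replicates=self.n_reps,
                )
            )
        return out


def outputs_to_dataset(
    outputs: Sequence[ABMOutput],
    observables: Sequence[str] | None = None,
    initial_count: float = 100.0,
) -> TimeSeriesDataset:
    """Bundle one or more dose arms of ABM output into a fit-ready dataset.

    By default every dose contributes a ``total_count`` arm plus the two
    compartment-count arms; nonzero doses additionally contribute a
    ``g2m_fraction`` arm (mirroring assays where cycle distributions are only
    measured under treatment).
    """
    arms: list[Arm] = []
    for out in outputs:
        if observables is None:
            obs = ["total_count", "g1s_count", "g2m_count"]
            if out.dose > 0:
                obs.append("g2m_fraction")
        else:
            obs = list(observables)
        arms.extend(out.arms(obs))
    return TimeSeriesDataset(arms=tuple(arms), provenance="abm", initial_count=initial_count)


def simulate(
    control: ABMControlParams,
    treat: ABMTreatmentParams | None = None,
    C: float = 0.0,
    t_grid: Sequence[float] = (0.0, 10.0, 24.0, 36.0, 48.0, 72.0),
    n_reps: int = 6,
    dt: float = 0.25,
    rng_seed: int = 0,
    n0: int = 100,
    init_phases: str = "stationary",
) -> ABMOutput:
    """Run ``n_reps`` independent replicates and record counts at ``t_grid``.

    Recording times must be (close to) integer multiples of ``dt``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    record_at = np.rint(t_grid / dt).astype(np.int64)
    if np.any(np.abs(record_at * dt - t_grid) > 1e-9 + 1e-6 * dt):
        raise ValueError("recording times must be integer multiples of dt")
    l, w = microenvironment_dims(control.K_A)
    if n0 > l * w:
        raise ValueError("n0 exceeds lattice capacity")

    p_adv = np.array([rate_to_step_probability(r, dt) for r in control.rhos])
    p_move = rate_to_step_probability(control.s, dt)
    if treat is not None and C > 0:
        p_arr_g1 = arrest_probability(C, treat.r_G1, treat.gamma1, treat.a)
        p_arr_g2 = arrest_probability(C, treat.r_G2, treat.gamma1, treat.a)
        p_die = rate_to_step_probability(
            apoptosis_rate(C, treat.delta_p, treat.gamma2, treat.b), dt
        )
    elif C < 0:
        raise ValueError("concentration must be nonnegative")
    else:
        p_arr_g1 = p_arr_g2 = p_die = 0.0
    if init_phases == "stationary":
        cdf = np.cumsum(stationary_phase_distribution(control.rhos))
    elif init_phases == "g1":
        cdf = np.array([1.0, 1.0, 1.0, 1.0])
    else:
        raise ValueError("init_phases must be 'stationary' or 'g1'")

    child_seeds = np.random.SeedSequence(rng_seed).generate_state(n_reps) % (2**31)
    counts = np.empty((n_reps, t_grid.size, 6), dtype=np.int64)
    for r in range(n_reps):
        counts[r] = _run_kernel(
            l, w, n0, int(child_seeds[r]), record_at,
            p_adv, p_arr_g1, p_arr_g2, p_move, p_die, int(control.T_con), cdf,
        )
    return ABMOutput(times=t_grid, counts=counts, dose=float(C), n0=n0, seed=rng_seed)
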