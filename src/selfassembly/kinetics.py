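"""Reaction propensities and exact stochastic simulation.

The reaction network (well-mixed, volume ``V = N/C``):

* dimerization — two free monomers of compatible species i, j nucleate a new
  cluster with propensity ``mu * n_i * n_j / V``;
* attachment — a frontier vacancy with ``b`` occupied neighbours accepts its
  species ``j`` with propensity ``b * nu * n_j / V`` (rate ``nu`` per bond
  formed);
* detachment — a removable member bound by ``n`` bonds leaves with Arrhenius
  rate ``delta_n = A * exp(-n * E_B)``, ``A = 1e18 * C * nu``;
* influx — species ``s`` is activated with propensity ``N * alpha`` while
  ``t`` lies in its supply window ``[T_s, T_s + 1/alpha]``.

Time is nondimensionalized so that with the default ``C = nu = 1`` it is
measured in units of ``(C*nu)**-1``.

``run_simulation`` is the single entry point: it dispatches to compiled
engines (``engine_ring`` for rings, ``engine_lattice`` for 2D/3D) or to the
transparent pure-Python reference loop in this file, which recomputes the
full propensity table every step and is the behavioural oracle for both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import StructureGeometry
from .state import (
    SystemState,
    apply_event,
    bond_count,
    removable_members,
)

__all__ = [
    "RateConstants",
    "PropensityTable",
    "Trajectory",
    "detachment_rate",
    "compute_propensities",
    "ssa_step",
    "run_simulation",
]

#: Arrhenius preexponential factor in units of C*nu.
PREEXPONENTIAL = 1e18


@dataclass(frozen=True)
class RateConstants:
    """Physical constants of a run (nondimensionalized, C = nu = 1 default)."""

    N: int  # copies per species
    C: float = 1.0  # concentration per species, C = N/V
    nu: float = 1.0  # attachment rate per binding site
    mu: float = 1.0  # dimerization rate constant
    E_B: float = math.inf  # binding energy per bond [k_B T]; inf = irreversible
    alpha: float = math.inf  # influx rate parameter; inf = instant supply
    T_i: tuple = ()  # per-species supply times (empty = all zero)

    @classmethod
    def create(cls, N, C=1.0, nu=1.0, mu=None, E_B=math.inf, alpha=math.inf, T_i=()):
        if N < 1:
            raise ValueError("N must be a positive integer")
        if C <= 0 or nu <= 0:
            raise ValueError("C and nu must be positive")
        return cls(
            N=int(N), C=float(C), nu=float(nu),
            mu=float(nu if mu is None else mu),
            E_B=float(E_B), alpha=float(alpha), T_i=tuple(T_i),
        )

    @property
    def V(self) -> float:
        """Reaction volume, V = N/C."""
        return self.N / self.C

    @property
    def A(self) -> float:
        """Detachment preexponential factor, A = 1e18 * C * nu."""
        return PREEXPONENTIAL * self.C * self.nu

    @property
    def delta1(self) -> float:
        """Single-bond detachment rate ``A * exp(-E_B)``."""
        return detachment_rate(1, self)


def detachment_rate(n: int, rates: RateConstants) -> float:
    """Arrhenius detachment rate ``A * exp(-n * E_B)`` for an n-bonded member."""
    if n < 1:
        raise ValueError("a bound monomer has at least one bond")
    if math.isinf(rates.E_B):
        return 0.0
    return rates.A * math.exp(-n * rates.E_B)


@dataclass
class PropensityTable:
    """Explicit event list with propensities (reference path, small systems)."""

    entries: list = field(default_factory=list)  # (kind, payload, propensity)
    total: float = 0.0

    def add(self, kind, payload, a):
        if a > 0.0:
            self.entries.append((kind, payload, a))
            self.total += a


def compute_propensities(
    state: SystemState, rates: RateConstants, geometry: StructureGeometry
) -> PropensityTable:
    """Full propensity table for the current state.

    An empty table (total = 0) signals a globally absorbing state.
    """
    table = PropensityTable()
    V = rates.V
    active = state.pools.active
    for i, j in geometry.bond_pairs():
        table.add(
            "dimerize", (i, j), rates.mu * active[i - 1] * active[j - 1] / V
        )
    for cluster in state.clusters:
        for site, b in sorted(cluster.frontier().items()):
            table.add(
                "attach", (cluster, site), b * rates.nu * active[site - 1] / V
            )
        if not math.isinf(rates.E_B):
            for site, n in sorted(removable_members(geometry, cluster).items()):
                table.add("detach", (cluster, site), detachment_rate(n, rates))
    if not math.isinf(rates.alpha):
        T_i = rates.T_i if rates.T_i else (0.0,) * geometry.S
        for s in range(1, geometry.S + 1):
            if (
                state.pools.unsupplied[s - 1] > 0
                and T_i[s - 1] <= state.t < T_i[s - 1] + 1.0 / rates.alpha
            ):
                table.add("influx", (s, 1), rates.N * rates.alpha)
    return table


def ssa_step(state, table: PropensityTable, rng, next_boundary=math.inf):
    """Draw (event, waiting time) by the direct Gillespie method.

    If the next influx-window or batch boundary arrives before the drawn
    waiting time, the step is truncated there and ``(None, boundary - t)``
    is returned so the caller can recompute propensities.
    """
    if table.total <= 0.0:
        raise ValueError("absorbing state: total propensity is zero")
    wait = rng.exponential(1.0 / table.total)
    if state.t + wait >= next_boundary:
        return None, next_boundary - state.t
    u = rng.random() * table.total
    acc = 0.0
    for kind, payload, a in table.entries:
        acc += a
        if u < acc:
            return (kind, *payload), wait
    kind, payload, _ = table.entries[-1]  # guard against rounding
    return (kind, *payload), wait


@dataclass
class Trajectory:
    """Event-subsampled time series of a single stochastic realization."""

    times: np.ndarray
    yields: np.ndarray
    n_clusters: np.ndarray
    free_monomers: np.ndarray
    completed: np.ndarray
    t90: float  # NaN if the target yield was never reached
    censored: bool
    final_time: float
    final_yield: float
    n_ref: int
    n_events: int
    event_counts: dict  # kind -> count
    seed: int
    final_state: tuple = None  # engine-specific diagnostics (mass audit)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "yield": self.yields,
                "n_clusters": self.n_clusters,
                "free_monomers_total": self.free_monomers,
                "completed": self.completed,
            }
        )

    def nucleation_events(self) -> int:
        return self.event_counts.get("dimerize", 0)

    def attachment_events(self) -> int:
        return self.event_counts.get("attach", 0)


def _supply_plan(config):
    """Normalize a ScenarioConfig into engine-ready supply arrays.

    Returns (active0, unsupplied0, batch_times, batch_species, batch_copies,
    window_start, window_end, window_rate).  Batches at t <= 0 are merged
    into the initial active pool.
    """
    S = config.geometry.S
    rates = config.rates
    active0 = np.zeros(S, dtype=np.int64)
    unsup0 = np.zeros(S, dtype=np.int64)
    bt, bs, bc = [], [], []
    ws = np.zeros(S)
    we = np.zeros(S)
    wr = np.zeros(S)
    if config.schedule is not None and math.isinf(rates.alpha):
        for t_i, entries in config.schedule.batches:
            for sp, copies in entries:
                if t_i <= 0.0:
                    active0[sp - 1] += copies
                else:
                    bt.append(t_i)
                    bs.append(sp)
                    bc.append(copies)
    elif not math.isinf(rates.alpha):
        T_i = rates.T_i if rates.T_i else (0.0,) * S
        tau = 1.0 / rates.alpha
        totals = (
            config.schedule.totals()
            if config.schedule is not None
            else np.full(S, rates.N, dtype=np.int64)
        )
        for s in range(S):
            unsup0[s] = totals[s]
            ws[s] = T_i[s]
            we[s] = T_i[s] + tau
            wr[s] = rates.N * rates.alpha
    else:
        active0[:] = rates.N
    order = np.argsort(np.asarray(bt, dtype=float), kind="stable")
    bt = np.asarray(bt, dtype=float)[order]
    bs = np.asarray(bs, dtype=np.int64)[order]
    bc = np.asarray(bc, dtype=np.int64)[order]
    return active0, unsup0, bt, bs, bc, ws, we, wr


def run_simulation(
    config,
    stop=None,
    seed: int = 0,
    engine: str = "auto",
    run_until: str = "target",
    checkpoint_every: int = 0,
) -> Trajectory:
    """Run one stochastic realization of a scenario.

    Parameters
    ----------
    config : ScenarioConfig
        Built by one of the :mod:`selfassembly.scenarios` constructors.
    stop : dict, optional
        ``target_yield`` (default 0.9), ``max_time`` (default inf) and
        ``max_events`` (default 2**62).  Exceeding ``max_time``/``max_events``
        censors the trajectory (flagged, not raised).
    seed : int
        Seed for all randomness; identical seeds give identical trajectories.
    engine : {"auto", "ring", "lattice", "reference"}
        ``auto`` picks the compiled ring engine for d=1, the compiled lattice
        engine for d>=2 without influx windows, else the reference loop.
    run_until : {"target", "end"}
        ``target`` stops at first yield >= target (T90 measurement);
        ``end`` continues to absorption or ``max_time`` (final-yield curves).
    """
    stop = dict(stop or {})
    target_yield = stop.get("target_yield", 0.9)
    max_time = stop.get("max_time", math.inf)
    max_events = int(stop.get("max_events", 2**62))
    if target_yield <= 0 or max_time <= 0 or max_events <= 0:
        raise ValueError("stop criteria must be positive")
    if run_until not in ("target", "end"):
        raise ValueError("run_until must be 'target' or 'end'")
    n_ref = config.n_ref
    target_completed = int(math.ceil(target_yield * n_ref))
    if engine == "auto":
        if config.geometry.d == 1:
            engine = "ring"
        elif math.isinf(config.rates.alpha):
            engine = "lattice"
        else:
            engine = "reference"
    if engine == "ring":
        from .engine_ring import run_ring

        return run_ring(
            config, target_completed, max_time, max_events, seed,
            run_until, checkpoint_every,
        )
    if engine == "lattice":
        from .engine_lattice import run_lattice

        return run_lattice(
            config, target_completed, max_time, max_events, seed,
            run_until, checkpoint_every,
        )
    if engine == "reference":
        return _run_reference(
            config, target_completed, max_time, max_events, seed, run_until
        )
    raise ValueError(f"unknown engine {engine!r}")


def _next_boundary(t, bt, ws, we, unsup):
    nb = math.inf
    for x in bt:
        if x > t:
            nb = min(nb, x)
            break
    for s in range(len(ws)):
        if unsup[s] > 0:
            if ws[s] > t:
                nb = min(nb, ws[s])
            elif we[s] > t:
                nb = min(nb, we[s])
    return nb


def _run_reference(config, target_completed, max_time, max_events, seed, run_until):
    """Direct-method SSA with full propensity recomputation every event."""
    geometry = config.geometry
    rates = config.rates
    active0, unsup0, bt, bs, bc, ws, we, wr = _supply_plan(config)
    state = SystemState.fresh(geometry, 0)
    state.pools.active = active0.copy()
    state.pools.unsupplied = unsup0.copy()
    for sp, cp in zip(bs, bc):  # future instantaneous batches await injection
        state.pools.unsupplied[sp - 1] += cp
    rng = np.random.default_rng(seed)
    n_ref = config.n_ref
    rec_t, rec_y, rec_c, rec_f, rec_n = [], [], [], [], []
    counts = {"dimerize": 0, "attach": 0, "detach": 0, "influx": 0}
    t90 = math.nan
    n_events = 0
    bptr = 0

    def record():
        rec_t.append(state.t)
        rec_y.append(state.completed / n_ref)
        rec_c.append(len(state.clusters))
        rec_f.append(int(state.pools.active.sum()))
        rec_n.append(state.completed)

    record()
    while True:
        # apply any due instantaneous batches / window flushes
        while bptr < len(bt) and bt[bptr] <= state.t:
            apply_event(state, ("influx", int(bs[bptr]), int(bc[bptr])))
            bptr += 1
        for s in range(geometry.S):
            if state.pools.unsupplied[s] > 0 and wr[s] > 0 and state.t >= we[s]:
                apply_event(state, ("influx", s + 1, int(state.pools.unsupplied[s])))
        if n_events >= max_events or state.t >= max_time:
            censored = math.isnan(t90)
            break
        table = compute_propensities(state, rates, geometry)
        nb = math.inf
        if bptr < len(bt):
            nb = bt[bptr]
        if not math.isinf(rates.alpha):
            nb = min(nb, _next_boundary(state.t, bt, ws, we, state.pools.unsupplied))
        if table.total <= 0.0:
            if math.isinf(nb):
                censored = math.isnan(t90)
                break
            state.t = nb
            continue
        event, wait = ssa_step(state, table, rng, next_boundary=nb)
        if event is None:
            state.t = nb
            continue
        if state.t + wait > max_time:
            state.t = max_time
            censored = math.isnan(t90)
            break
        state.t += wait
        apply_event(state, event)
        counts[event[0]] += 1
        n_events += 1
        if event[0] in ("dimerize", "attach") and state.completed and (
            rec_n[-1] != state.completed
        ):
            record()
            if math.isnan(t90) and state.completed >= target_completed:
                t90 = state.t
                if run_until == "target":
                    censored = False
                    break
    record()
    return Trajectory(
        times=np.asarray(rec_t),
        yields=np.asarray(rec_y),
        n_clusters=np.asarray(rec_c, dtype=np.int64),
        free_monomers=np.asarray(rec_f, dtype=np.int64),
        completed=np.asarray(rec_n, dtype=np.int64),
        t90=t90,
        censored=censored,
        final_time=state.t,
        final_yield=state.completed / n_ref,
        n_ref=n_ref,
        n_events=n_events,
        event_counts=counts,
        seed=seed,
    )
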