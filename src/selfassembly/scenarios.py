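"""Scenario configurations: the four ways of controlling assembly.

Each builder fixes every parameter except the scenario's own control to the
defaults ``T_i = 0, alpha = inf, mu = nu, E_B = inf`` (irreversible,
instantaneous, barrier-free), and deviates only in its control parameter:

* ``reversible``    — binding energy ``E_B`` (finite detachment rates);
* ``dimerization``  — nucleation rate ratio ``mu/nu``;
* ``activation``    — influx rate ``alpha`` (supply spread over ``1/alpha``);
* ``jis``           — batch interval ``Delta_T`` of the just-in-sequence
  supply schedule (onion shells for d >= 2, linear sequence for d = 1),
  optionally with a nonstoichiometric linear copy-number ramp
  (0.9 N for the first species up to 1.1 N for the last) and multiplicative
  supply noise of a given coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import RateConstants
from .lattice import StructureGeometry, onion_shells

__all__ = [
    "ScenarioConfig",
    "SupplySchedule",
    "jis_batches",
    "make_reversible",
    "make_dimerization",
    "make_activation",
    "make_jis",
    "apply_supply_noise",
]


def jis_batches(geometry: StructureGeometry) -> list:
    """Supply batches for just-in-sequence delivery.

    Refines the geometric onion shells so that no batch contains two
    mutual binding partners — simultaneous supply of compatible species
    would nucleate competing defect dimers within the batch and collapse
    the yield of higher-dimensional targets.  Starting from a single seed
    site, each shell is emitted as a deterministic sequence of greedy
    independent sets whose members are all adjacent to already-supplied
    sites, so growth stays radial and single-nucleus per structure.
    For d = 1 this reduces to the singleton linear sequence.
    """
    shells = onion_shells(geometry)
    adj = geometry.adjacency
    batches: list = [[shells[0][0]]]
    supplied = set(batches[0])
    pending: list = [s for s in shells[0] if s not in supplied]
    for shell in shells[1:] + [[]]:
        while pending:
            candidates = [
                s for s in pending if any(t in supplied for t in adj[s - 1])
            ]
            if not candidates:
                break
            batch: list = []
            taken: set = set()
            for s in candidates:
                if not any(t in taken for t in adj[s - 1]):
                    batch.append(s)
                    taken.add(s)
            batches.append(batch)
            supplied |= taken
            pending = [s for s in pending if s not in taken]
        pending.extend(shell)
    if pending:  # any stragglers (cannot occur for cubic lattices)
        batches.append(sorted(pending))
    return batches


@dataclass(frozen=True)
class SupplySchedule:
    """Ordered supply batches: (time T_i, [(species, copies), ...])."""

    batches: tuple

    def __post_init__(self):
        times = [t for t, _ in self.batches]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("batch times must be strictly increasing")

    def totals(self) -> np.ndarray:
        """Per-species total supplied copies (index s-1 for species s)."""
        n = max(sp for _, entries in self.batches for sp, _ in entries)
        out = np.zeros(n, dtype=np.int64)
        for _, entries in self.batches:
            for sp, copies in entries:
                out[sp - 1] += copies
        return out

    def supply_rank(self) -> dict:
        """Species -> 1-based position in the flattened supply order."""
        rank = {}
        r = 1
        for _, entries in self.batches:
            for sp, _ in entries:
                rank[sp] = r
                r += 1
        return rank

    def to_frame(self):
        import pandas as pd

        rows = [
            (b, t, sp, copies)
            for b, (t, entries) in enumerate(self.batches, start=1)
            for sp, copies in entries
        ]
        return pd.DataFrame(rows, columns=["batch", "time", "species", "copies"])


@dataclass(frozen=True)
class ScenarioConfig:
    """A fully specified run: geometry + rates + scenario control + supply."""

    geometry: StructureGeometry
    rates: RateConstants
    scenario: str  # reversible | dimerization | activation | jis
    control: dict = field(default_factory=dict)
    schedule: SupplySchedule = None
    ramp: str = "stoichiometric"

    @property
    def n_ref(self) -> int:
        """Yield denominator: the minimum per-species supplied allotment.

        Equals N under stoichiometric supply; under the nonstoichiometric
        ramp the first species caps completions at 0.9 N, so the reference
        is the minimum supplied count and a yield of 1 stays attainable.
        """
        if self.schedule is None:
            return self.rates.N
        totals = self.schedule.totals()
        totals = totals[totals > 0]
        return int(totals.min())


def _single_batch(geometry: StructureGeometry, N: int) -> SupplySchedule:
    entries = tuple((s, int(N)) for s in range(1, geometry.S + 1))
    return SupplySchedule(batches=((0.0, entries),))


def make_reversible(geometry, E_B, N, C=1.0, nu=1.0) -> ScenarioConfig:
    """Reversible-binding scenario: finite ``E_B`` controls detachment.

    All monomers are supplied at t = 0 with ``mu = nu``; detachment is
    active with rate ``delta_n = A exp(-n E_B)``, ``A = 1e18 C nu``.
    """
    if not (math.isfinite(E_B) and E_B > 0):
        raise ValueError(
            "reversible scenario needs a finite positive binding energy "
            "(E_B = inf is the irreversible default, not a scenario control)"
        )
    rates = RateConstants.create(N=N, C=C, nu=nu, mu=nu, E_B=E_B)
    return ScenarioConfig(
        geometry=geometry, rates=rates, scenario="reversible",
        control={"E_B": float(E_B)}, schedule=_single_batch(geometry, N),
    )


def make_dimerization(geometry, mu_over_nu, N, C=1.0, nu=1.0) -> ScenarioConfig:
    """Dimerization scenario: the nucleation barrier ``mu/nu`` is the control."""
    if mu_over_nu <= 0:
        raise ValueError("mu/nu must be positive")
    rates = RateConstants.create(N=N, C=C, nu=nu, mu=mu_over_nu * nu)
    return ScenarioConfig(
        geometry=geometry, rates=rates, scenario="dimerization",
        control={"mu_over_nu": float(mu_over_nu)},
        schedule=_single_batch(geometry, N),
    )


def make_activation(geometry, alpha, N, C=1.0, nu=1.0) -> ScenarioConfig:
    """Activation scenario: every species flows in over ``[0, 1/alpha]``
    at rate ``N * alpha``; decreasing ``alpha`` throttles the momentary
    free-monomer concentration and with it the effective nucleation rate."""
    if not (alpha > 0 and math.isfinite(alpha)):
        raise ValueError("alpha must be finite and positive")
    rates = RateConstants.create(N=N, C=C, nu=nu, mu=nu, alpha=alpha)
    return ScenarioConfig(
        geometry=geometry, rates=rates, scenario="activation",
        control={"alpha": float(alpha)},
    )


def make_jis(
    geometry, delta_T, N, ramp="stoichiometric", nu=1.0, C=1.0,
) -> ScenarioConfig:
    """Just-in-sequence scenario: batches at equidistant times ``(k-1) dT``.

    Batch membership follows :func:`selfassembly.lattice.onion_shells`
    (linear sequence in 1D, concentric shells for d >= 2).  Under
    ``ramp="linear"`` the species at supply rank r of S receives
    ``round(N * (0.9 + 0.2 * (r-1)/(S-1)))`` copies — 0.9 N for the first
    species up to 1.1 N for the last; ``ramp="stoichiometric"`` supplies
    N copies of every species.
    """
    if delta_T <= 0:
        raise ValueError("batch interval Delta_T must be positive")
    if ramp not in ("stoichiometric", "linear"):
        raise ValueError(f"unknown ramp {ramp!r}")
    S = geometry.S
    if S == 1:
        ramp = "stoichiometric"
    shells = jis_batches(geometry)
    rank = {}
    r = 1
    for shell in shells:
        for sp in shell:
            rank[sp] = r
            r += 1

    def copies(sp):
        if ramp == "stoichiometric":
            return int(N)
        return int(round(N * (0.9 + 0.2 * (rank[sp] - 1) / (S - 1))))

    batches = tuple(
        ((k) * float(delta_T), tuple((sp, copies(sp)) for sp in shell))
        for k, shell in enumerate(shells)
    )
    # first batch at time 0; SupplySchedule forbids non-increasing times
    rates = RateConstants.create(N=N, C=C, nu=nu, mu=nu)
    return ScenarioConfig(
        geometry=geometry, rates=rates, scenario="jis",
        control={"delta_T": float(delta_T)},
        schedule=SupplySchedule(batches=batches), ramp=ramp,
    )


def apply_supply_noise(schedule: SupplySchedule, cv: float, rng) -> SupplySchedule:
    """Perturb every species' copy count by an independent factor (1 + eps),
    eps ~ Normal(0, cv), rounded and clamped at zero.

    Models extrinsic pipetting/concentration noise in the supplied amounts.
    """
    if cv < 0:
        raise ValueError("coefficient of variation must be >= 0")
    if cv == 0:
        return schedule
    batches = []
    for t, entries in schedule.batches:
        new_entries = []
        for sp, copies in entries:
            factor = 1.0 + cv * rng.standard_normal()
            new_entries.append((sp, max(0, int(round(copies * factor)))))
        batches.append((t, tuple(new_entries)))
    return SupplySchedule(batches=tuple(batches))
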