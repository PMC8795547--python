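"""Species-symmetric rate equations for 1D ring assembly.

In the limit of large copy numbers the species identity of the building
blocks is irrelevant for the simultaneous-supply scenarios, so the 1D
dynamics close on the cluster-size distribution: a shared free-monomer
concentration ``m`` per species and concentrations ``c_k`` of clusters of
size ``k`` (k = 2 .. S-1), with completed rings ``y``:

* nucleation        J     = S * mu * m**2           (S ring pairs),
* growth            a_k   = 2 * nu * m * c_k        (two ends, one specific
  species each at concentration m; the ring-closing step k = S-1 sees the
  same 2*nu*m because its single vacancy forms two bonds),
* shrinkage         b_k   = 2 * delta * c_k         (two singly-bonded ends;
  dimer breakup returns both monomers).

The monomer balance divides total fluxes by S because each species supplies
an equal share.  Mass ``S*m + sum_k k*c_k + S*y`` is conserved identically.

This deterministic integrator is a fast cross-check oracle for the
stochastic engine (1D dimerization/activation/reversible only; species
identity is essential for just-in-sequence supply, which has no symmetric
reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["SizeDistribution", "bd_rhs", "integrate"]


@dataclass
class SizeDistribution:
    """State of the size-resolved rate equations at one time point."""

    t: float
    m: float  # free monomer concentration per species
    c: np.ndarray  # c[k-2] = concentration of k-clusters, k = 2..S-1
    y: float  # concentration of completed rings

    def mass(self, S: int) -> float:
        k = np.arange(2, S)
        return S * self.m + float((k * self.c).sum()) + S * self.y


def bd_rhs(dist: SizeDistribution, params: dict) -> SizeDistribution:
    """Time derivatives of (m, c_k, y) for the closed 1D system.

    ``params`` holds mu, nu, delta, S, C and optionally ``influx`` (a source
    term dm/dt += C*alpha active while t < 1/alpha, for the activation
    cross-check).
    """
    S = params["S"]
    du = _rhs(
        dist.t,
        np.concatenate(([dist.m], dist.c, [dist.y])),
        params["mu"], params["nu"], params["delta"], S,
        params.get("influx_rate", 0.0), params.get("influx_end", 0.0),
    )
    return SizeDistribution(t=dist.t, m=du[0], c=du[1:-1], y=du[-1])


def _rhs(t, u, mu, nu, delta, S, influx_rate, influx_end):
    m = max(u[0], 0.0)  # guard against tiny negative solver excursions
    if S == 2:
        J = mu * m * m  # single compatible pair on the degenerate ring
        dm = -J
        if influx_rate > 0.0 and t < influx_end:
            dm += influx_rate
        return np.array([dm, J])
    c = np.maximum(u[1:-1], 0.0)
    J = S * mu * m * m
    a = 2.0 * nu * m * c  # growth fluxes a_k, k = 2..S-1
    b = 2.0 * delta * c  # shrink fluxes b_k, k = 2..S-1
    dc = np.empty_like(c)
    dc[0] = J - a[0] - b[0]
    dc[1:] = a[:-1] - a[1:] - b[1:]
    dc[:-1] += b[1:]  # b_{k+1} feeds c_k (k <= S-2)
    dy = a[-1]
    dm = -2.0 * J / S - a.sum() / S + (b[1:].sum() + 2.0 * b[0]) / S
    if influx_rate > 0.0 and t < influx_end:
        dm += influx_rate
    return np.concatenate(([dm], dc, [dy]))


def integrate(
    params: dict,
    t_end: float,
    tolerances=(1e-8, 1e-10),
    target_yield: float = 0.9,
    alpha: float = math.inf,
):
    """Integrate the rate equations from pristine monomers.

    Parameters
    ----------
    params : dict with mu, nu, delta, S, C
    t_end : float
        Integration horizon (time units of (C*nu)^-1).
    tolerances : (rtol, atol)
    target_yield : float
        The crossing ``y/C >= target_yield`` defines T90 (interpolated by
        the integrator's event location; NaN if never reached).
    alpha : float
        Finite value switches on the activation source term: monomers enter
        at concentration rate C*alpha until t = 1/alpha (initial m = 0).

    Returns
    -------
    (trajectory, t90) : (list of SizeDistribution, float)
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    S, C = params["S"], params["C"]
    mu, nu, delta = params["mu"], params["nu"], params["delta"]
    n = 2 if S == 2 else S  # state size: m, c_2..c_{S-1}, y
    u0 = np.zeros(n)
    if math.isinf(alpha):
        influx_rate, influx_end = 0.0, 0.0
        u0[0] = C
    else:
        influx_rate, influx_end = C * alpha, 1.0 / alpha

    def rhs(t, u):
        return _rhs(t, u, mu, nu, delta, S, influx_rate, influx_end)

    def hit_target(t, u):
        return u[-1] / C - target_yield

    hit_target.terminal = False
    hit_target.direction = 1.0
    rtol, atol = tolerances
    sol = solve_ivp(
        rhs, (0.0, t_end), u0, method="LSODA", rtol=rtol, atol=atol,
        events=hit_target, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    t90 = float(sol.t_events[0][0]) if len(sol.t_events[0]) else math.nan
    traj = [
        SizeDistribution(
            t=float(tt), m=float(uu[0]),
            c=uu[1:-1].copy() if S > 2 else np.empty(0),
            y=float(uu[-1]),
        )
        for tt, uu in zip(sol.t, sol.y.T)
    ]
    drift = abs(traj[-1].mass(S) - S * C) / (S * C) if math.isinf(alpha) else None
    if drift is not None and drift > 1e-6:
        raise RuntimeError(f"mass conservation drift {drift:.2e} exceeds 1e-6")
    return traj, t90
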