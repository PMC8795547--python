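"""System configuration and event bookkeeping.

The instantaneous state of the well-mixed assembly system consists of the
free-monomer pools (active and not-yet-supplied copies per species), the
growing clusters — connected partial copies of the target structure — and
the count of completed structures.  Events (dimerization, attachment,
detachment, influx) are applied with strict integer mass accounting.

Single monomers live in the pools, never as one-member clusters: clusters
are nucleated by dimerization and always hold at least two members.  A
cluster that contains all S species is complete and leaves the reactive set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import StructureGeometry

__all__ = [
    "MonomerPools",
    "Cluster",
    "SystemState",
    "bond_count",
    "removable_members",
    "apply_event",
    "yield_of",
]


@dataclass
class MonomerPools:
    """Free-monomer copy counts per species (1-based indexing via arrays)."""

    active: np.ndarray  # assembly-competent free monomers
    unsupplied: np.ndarray  # not yet injected (activation / JIS)

    @classmethod
    def full(cls, S: int, N: int) -> "MonomerPools":
        return cls(np.full(S, N, dtype=np.int64), np.zeros(S, dtype=np.int64))

    @classmethod
    def empty(cls, S: int, N: int) -> "MonomerPools":
        return cls(np.zeros(S, dtype=np.int64), np.full(S, N, dtype=np.int64))

    def copy(self) -> "MonomerPools":
        return MonomerPools(self.active.copy(), self.unsupplied.copy())


class Cluster:
    """A connected set of occupied target-structure sites.

    Parameters
    ----------
    geometry : StructureGeometry
    members : iterable of int
        1-based species labels present in the cluster (>= 2 of them, forming
        a connected subgraph of the geometry).
    """

    __slots__ = ("geometry", "members")

    def __init__(self, geometry: StructureGeometry, members):
        self.geometry = geometry
        self.members = set(members)
        if len(self.members) < 2:
            raise ValueError("a cluster holds at least two members")
        if not self._connected(self.members):
            raise ValueError("cluster members must form a connected subgraph")

    def _connected(self, members) -> bool:
        members = set(members)
        if not members:
            return True
        adj = self.geometry.adjacency
        stack = [next(iter(members))]
        seen = {stack[0]}
        while stack:
            s = stack.pop()
            for t in adj[s - 1]:
                if t in members and t not in seen:
                    seen.add(t)
                    stack.append(t)
        return seen == members

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def complete(self) -> bool:
        return len(self.members) == self.geometry.S

    def frontier(self) -> dict:
        """Vacancies adjacent to the cluster, mapped to their bond count b."""
        out: dict = {}
        adj = self.geometry.adjacency
        for m in self.members:
            for t in adj[m - 1]:
                if t not in self.members:
                    out[t] = out.get(t, 0) + 1
        return out

    def member_bonds(self, site: int) -> int:
        """Number of bonds a member currently forms."""
        if site not in self.members:
            raise ValueError(f"species {site} is not a member")
        return sum(1 for t in self.geometry.adjacency[site - 1] if t in self.members)

    def articulation_points(self) -> set:
        """Members whose removal would disconnect the cluster (iterative DFS)."""
        members = self.members
        if len(members) <= 2:
            return set()
        adj = self.geometry.adjacency
        root = next(iter(members))
        disc: dict = {}
        low: dict = {}
        parent: dict = {root: None}
        arts: set = set()
        stack = [(root, iter([t for t in adj[root - 1] if t in members]))]
        disc[root] = low[root] = 0
        timer = 1
        root_children = 0
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if child not in disc:
                    parent[child] = node
                    disc[child] = low[child] = timer
                    timer += 1
                    if node == root:
                        root_children += 1
                    stack.append(
                        (child, iter([t for t in adj[child - 1] if t in members]))
                    )
                    advanced = True
                    break
                elif child != parent[node]:
                    low[node] = min(low[node], disc[child])
            if not advanced:
                stack.pop()
                p = parent[node]
                if p is not None:
                    low[p] = min(low[p], low[node])
                    if p != root and low[node] >= disc[p]:
                        arts.add(p)
        if root_children > 1:
            arts.add(root)
        return arts

    def copy(self) -> "Cluster":
        c = Cluster.__new__(Cluster)
        c.geometry = self.geometry
        c.members = set(self.members)
        return c


def bond_count(geometry: StructureGeometry, cluster: Cluster, site: int) -> int:
    """Bonds a monomer would form by attaching at the vacancy ``site``."""
    if site in cluster.members:
        raise ValueError(f"site {site} is occupied")
    if not 1 <= site <= geometry.S:
        raise ValueError(f"species index {site} outside 1..{geometry.S}")
    return sum(1 for t in geometry.adjacency[site - 1] if t in cluster.members)


def removable_members(geometry: StructureGeometry, cluster: Cluster) -> dict:
    """Members eligible for detachment, mapped to their bond count n.

    Only members whose removal keeps the cluster connected may detach
    (clusters never fragment); for a linear chain these are exactly the two
    ends, each bound by a single bond.
    """
    arts = cluster.articulation_points()
    return {
        m: cluster.member_bonds(m) for m in cluster.members if m not in arts
    }


@dataclass
class SystemState:
    """Simulation clock, pools, live clusters and completed-structure count."""

    geometry: StructureGeometry
    pools: MonomerPools
    clusters: list = field(default_factory=list)
    completed: int = 0
    t: float = 0.0

    @classmethod
    def fresh(cls, geometry: StructureGeometry, N: int, supplied: bool = True):
        pools = (
            MonomerPools.full(geometry.S, N)
            if supplied
            else MonomerPools.empty(geometry.S, N)
        )
        return cls(geometry=geometry, pools=pools)

    def species_mass(self) -> np.ndarray:
        """Per-species total copies (active + unsupplied + bound + completed)."""
        mass = self.pools.active + self.pools.unsupplied
        for c in self.clusters:
            for m in c.members:
                mass[m - 1] += 1
        return mass + self.completed

    def copy(self) -> "SystemState":
        return SystemState(
            geometry=self.geometry,
            pools=self.pools.copy(),
            clusters=[c.copy() for c in self.clusters],
            completed=self.completed,
            t=self.t,
        )


def apply_event(state: SystemState, event: tuple) -> SystemState:
    """Apply a feasible event in place and return the state.

    ``event`` is one of::

        ("dimerize", i, j)           two compatible free monomers nucleate
        ("attach", cluster, site)    a free monomer joins at a frontier site
        ("detach", cluster, site)    a removable member returns to the pool
        ("influx", species, amount)  unsupplied copies become active

    A cluster reaching all S species increments ``completed`` and leaves the
    reactive set; a dimer losing a member dissolves into two free monomers.
    Raises ``ValueError`` identifying the violated precondition otherwise.
    """
    kind = event[0]
    pools = state.pools
    if kind == "dimerize":
        _, i, j = event
        if j not in state.geometry.adjacency[i - 1]:
            raise ValueError(f"species {i} and {j} are not binding partners")
        if pools.active[i - 1] < 1 or pools.active[j - 1] < 1:
            raise ValueError("dimerization needs one active copy of each species")
        pools.active[i - 1] -= 1
        pools.active[j - 1] -= 1
        cluster = Cluster(state.geometry, (i, j))
        if cluster.complete:  # S = 2 degenerate ring
            state.completed += 1
        else:
            state.clusters.append(cluster)
    elif kind == "attach":
        _, cluster, site = event
        if cluster not in state.clusters:
            raise ValueError("attach target is not a live cluster")
        if bond_count(state.geometry, cluster, site) < 1:
            raise ValueError(f"site {site} is not on the cluster frontier")
        if pools.active[site - 1] < 1:
            raise ValueError(f"no active copy of species {site}")
        pools.active[site - 1] -= 1
        cluster.members.add(site)
        if cluster.complete:
            state.clusters.remove(cluster)
            state.completed += 1
    elif kind == "detach":
        _, cluster, site = event
        if cluster not in state.clusters:
            raise ValueError("detach target is not a live cluster")
        if site not in removable_members(state.geometry, cluster):
            raise ValueError(f"member {site} is not removable")
        cluster.members.remove(site)
        pools.active[site - 1] += 1
        if cluster.size == 1:
            (rest,) = cluster.members
            pools.active[rest - 1] += 1
            state.clusters.remove(cluster)
    elif kind == "influx":
        _, species, amount = event
        if amount < 1 or pools.unsupplied[species - 1] < amount:
            raise ValueError("influx exceeds the unsupplied allotment")
        pools.unsupplied[species - 1] -= amount
        pools.active[species - 1] += amount
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return state


def yield_of(state: SystemState, reference_count: int) -> float:
    """Completed structures relative to their maximum possible number."""
    if reference_count <= 0:
        raise ValueError("reference count must be positive")
    return state.completed / reference_count
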