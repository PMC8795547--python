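"""Target-structure geometry.

A target structure is a fully heterogeneous lattice: every one of the
``S = L**d`` sites is occupied by a distinct monomer species, and binding is
only possible between species whose sites are nearest neighbours.  Linear
structures (d=1) are closed rings (periodic boundary), so every species has
exactly two binding partners; sheets (d=2) and cubes (d=3) have open
boundaries, so boundary species have a reduced number of partners.

Species are labelled 1..S in row-major site order; site coordinates are
0-based integer tuples in ``[0, L)**d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["StructureGeometry", "build_geometry", "neighbors", "onion_shells"]


@dataclass(frozen=True)
class StructureGeometry:
    """Geometry of the target structure.

    Attributes
    ----------
    d : int
        Dimensionality (1, 2 or 3).
    L : int
        Edge length; the structure has ``S = L**d`` sites.
    S : int
        Total number of species / sites.
    boundary : str
        ``"periodic"`` for d=1 (ring), ``"open"`` otherwise.
    adjacency : tuple[tuple[int, ...], ...]
        ``adjacency[s-1]`` lists the 1-based species adjacent to species s.
    """

    d: int
    L: int
    S: int
    boundary: str
    adjacency: tuple = field(repr=False)

    def coords(self, species: int) -> tuple:
        """0-based lattice coordinates of a 1-based species label."""
        _check_site(self, species)
        idx = species - 1
        out = []
        for _ in range(self.d):
            out.append(idx % self.L)
            idx //= self.L
        return tuple(reversed(out))

    def species_at(self, coords) -> int:
        """Inverse of :meth:`coords` (row-major, 1-based)."""
        idx = 0
        for c in coords:
            if not 0 <= c < self.L:
                raise ValueError(f"coordinate {coords} outside [0, {self.L})^{self.d}")
            idx = idx * self.L + c
        return idx + 1

    @property
    def n_bonds(self) -> int:
        """Number of lattice bonds (= compatible species pairs)."""
        return sum(len(a) for a in self.adjacency) // 2

    def bond_pairs(self) -> list:
        """All compatible (i, j) species pairs with i < j."""
        return [
            (i, j)
            for i in range(1, self.S + 1)
            for j in self.adjacency[i - 1]
            if i < j
        ]


def build_geometry(d: int, L: int) -> StructureGeometry:
    """Construct the geometry of a d-dimensional target of edge length L.

    d=1 gives a periodic ring of S=L species (species 1 and S bind); d=2/3
    give open-boundary square/cubic lattices, so interior sites have 2d
    neighbours while boundary sites have fewer.

    Raises
    ------
    ValueError
        If ``d`` is not 1, 2 or 3, or ``L < 2``.
    """
    if d not in (1, 2, 3):
        raise ValueError(f"dimension must be 1, 2 or 3, got {d!r}")
    if not isinstance(L, (int, np.integer)) or L < 2:
        raise ValueError(f"edge length must be an integer >= 2, got {L!r}")
    L = int(L)
    S = L**d
    adjacency: list = []
    if d == 1:
        if S == 2:
            # Degenerate ring: the two species form a single compatible pair.
            adjacency = [(2,), (1,)]
        else:
            adjacency = [((i - 2) % S + 1, i % S + 1) for i in range(1, S + 1)]
        boundary = "periodic"
    else:
        boundary = "open"
        for coords in product(range(L), repeat=d):
            nbrs = []
            for axis in range(d):
                for step in (-1, 1):
                    c2 = list(coords)
                    c2[axis] += step
                    if 0 <= c2[axis] < L:
                        idx = 0
                        for c in c2:
                            idx = idx * L + c
                        nbrs.append(idx + 1)
            adjacency.append(tuple(sorted(nbrs)))
    return StructureGeometry(
        d=d, L=L, S=S, boundary=boundary, adjacency=tuple(tuple(a) for a in adjacency)
    )


def _check_site(geometry: StructureGeometry, site: int) -> None:
    if not 1 <= site <= geometry.S:
        raise ValueError(f"species index {site} outside 1..{geometry.S}")


def neighbors(geometry: StructureGeometry, site: int) -> list:
    """Compatible binding partners (1-based species labels) of ``site``."""
    _check_site(geometry, site)
    return list(geometry.adjacency[site - 1])


def onion_shells(geometry: StructureGeometry) -> list:
    """Partition the sites into ordered supply batches for radial growth.

    For d=1 the batches are the singletons 1, 2, ..., S (unidirectional
    linear sequence).  For d>=2 the batches are concentric Chebyshev shells
    around the centre, so that structures supplied batch-by-batch grow
    radially like onion skins.  For odd L the seed is the single central
    site; for even L the central ``2**d`` block is emitted first, split into
    ``d+1`` sub-batches (by Manhattan distance from one corner of the block)
    so that no seed batch contains two adjacent sites.

    Every non-seed batch is entirely adjacent to the union of the earlier
    batches, so each batch can attach to already-present material.
    """
    if geometry.d == 1:
        return [[s] for s in range(1, geometry.S + 1)]

    L, d = geometry.L, geometry.d
    if L % 2 == 1:
        c = L // 2
        center = [c] * d

        def shell_of(coords):
            return max(abs(x - c) for x in coords)

        n_shells = c + 1
        batches: list = [[] for _ in range(n_shells)]
        for coords in product(range(L), repeat=d):
            batches[shell_of(coords)].append(geometry.species_at(coords))
        return [sorted(b) for b in batches]

    # Even L: central block spans indices {L//2 - 1, L//2} on each axis.
    lo, hi = L // 2 - 1, L // 2

    def block_dist(coords):
        dist = 0
        for x in coords:
            if x < lo:
                dist = max(dist, lo - x)
            elif x > hi:
                dist = max(dist, x - hi)
        return dist

    n_shells = lo + 1
    shells: list = [[] for _ in range(n_shells)]
    for coords in product(range(L), repeat=d):
        shells[block_dist(coords)].append(coords)
    # Split the seed block into d+1 adjacency-free sub-batches.
    seed_sub: list = [[] for _ in range(d + 1)]
    for coords in shells[0]:
        manh = sum(x - lo for x in coords)
        seed_sub[manh].append(geometry.species_at(coords))
    batches = [sorted(b) for b in seed_sub]
    for shell in shells[1:]:
        batches.append(sorted(geometry.species_at(c) for c in shell))
    return batches
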