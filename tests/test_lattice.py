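"""Geometry: neighbour relations, boundary coordination, onion shells."""

import pytest
from hypothesis import given, settings, strategies as st

from selfassembly.lattice import build_geometry, neighbors, onion_shells


@settings(max_examples=40, derandomize=True, deadline=None)
@given(d=st.integers(1, 3), L=st.integers(2, 6))
def test_coordination_bounds_property(d, L):
    """Coordination is between d (corner, open) and 2d everywhere, and the
    coordinate mapping is a bijection."""
    g = build_geometry(d, L)
    # degenerate 2-ring: the pair counts as one bond, so one neighbour each
    lo = (1 if L == 2 else 2) if d == 1 else d
    seen = set()
    for s in range(1, g.S + 1):
        assert lo <= len(neighbors(g, s)) <= 2 * d
        c = g.coords(s)
        assert g.species_at(c) == s
        seen.add(c)
    assert len(seen) == g.S


@pytest.mark.parametrize("d,L", [(1, 2), (1, 5), (1, 16), (2, 2), (2, 3),
                                 (2, 5), (3, 2), (3, 3)])
def test_geometry_invariants(d, L):
    g = build_geometry(d, L)
    assert g.S == L**d
    # symmetry and irreflexivity
    for s in range(1, g.S + 1):
        nb = neighbors(g, s)
        assert s not in nb
        assert len(set(nb)) == len(nb)
        for t in nb:
            assert s in neighbors(g, t)
    # total coordination = 2 * number of bonds
    total = sum(len(neighbors(g, s)) for s in range(1, g.S + 1))
    if d == 1:
        expected_bonds = g.S if g.S > 2 else 1
    elif d == 2:
        expected_bonds = 2 * L * (L - 1)
    else:
        expected_bonds = 3 * L * L * (L - 1)
    assert total == 2 * expected_bonds
    assert g.n_bonds == expected_bonds


def test_ring_is_periodic():
    g = build_geometry(1, 5)
    for s in range(1, 6):
        assert set(neighbors(g, s)) == {(s - 2) % 5 + 1, s % 5 + 1}
    # species 1 and S bind
    assert 5 in neighbors(g, 1)


def test_open_boundary_coordination():
    g = build_geometry(2, 10)
    counts = sorted(len(neighbors(g, s)) for s in range(1, 101))
    assert counts.count(2) == 4  # corners
    assert counts.count(3) == 4 * 8  # edges
    assert counts.count(4) == 64  # interior
    g3 = build_geometry(3, 2)
    assert all(len(neighbors(g3, s)) == 3 for s in range(1, 9))
    g33 = build_geometry(3, 3)
    center = g33.species_at((1, 1, 1))
    assert len(neighbors(g33, center)) == 6


def test_corner_site_2d():
    g = build_geometry(2, 3)
    corner = g.species_at((0, 0))
    assert len(neighbors(g, corner)) == 2
    center = g.species_at((1, 1))
    assert set(neighbors(g, center)) == {
        g.species_at((0, 1)), g.species_at((2, 1)),
        g.species_at((1, 0)), g.species_at((1, 2)),
    }


@pytest.mark.parametrize("d,L,msg", [(0, 3, "dimension"), (4, 3, "dimension"),
                                     (2, 1, "edge length"), (1, 0, "edge length")])
def test_invalid_geometry_rejected(d, L, msg):
    with pytest.raises(ValueError, match=msg):
        build_geometry(d, L)


def test_out_of_range_site_rejected(ring8):
    with pytest.raises(ValueError):
        neighbors(ring8, 0)
    with pytest.raises(ValueError):
        neighbors(ring8, 9)


def test_onion_shell_sizes():
    assert [len(b) for b in onion_shells(build_geometry(2, 5))] == [1, 8, 16]
    assert [len(b) for b in onion_shells(build_geometry(3, 3))] == [1, 26]
    assert onion_shells(build_geometry(1, 6)) == [[1], [2], [3], [4], [5], [6]]


@pytest.mark.parametrize("d,L", [(1, 6), (2, 3), (2, 4), (2, 5), (3, 2),
                                 (3, 3), (3, 4)])
def test_onion_shells_partition_and_growth(d, L):
    g = build_geometry(d, L)
    batches = onion_shells(g)
    flat = [s for b in batches for s in b]
    assert sorted(flat) == list(range(1, g.S + 1))  # exact partition
    assert all(batches)  # no empty shell
    # radial growth: the union of the first k shells is always connected
    # (corner sites of a Chebyshev shell touch their own shell, so full
    # shell-to-earlier adjacency holds only after the just-in-sequence
    # subdivision, tested in test_scenarios)
    seen = set(batches[0])
    for batch in batches[1:]:
        assert any(
            t in seen for s in batch for t in neighbors(g, s)
        )  # each shell touches the grown core
        seen |= set(batch)
        # connectivity of the supplied region by flood fill
        stack = [next(iter(seen))]
        comp = {stack[0]}
        while stack:
            s = stack.pop()
            for t in neighbors(g, s):
                if t in seen and t not in comp:
                    comp.add(t)
                    stack.append(t)
        assert comp == seen


@pytest.mark.parametrize("d,L", [(2, 2), (2, 4), (3, 2)])
def test_even_seed_block_has_no_adjacent_pairs(d, L):
    g = build_geometry(d, L)
    batches = onion_shells(g)
    # the central 2**d block is split into d+1 adjacency-free sub-batches
    seed = batches[: d + 1]
    assert sum(len(b) for b in seed) == 2**d
    for batch in seed:
        for s in batch:
            assert not any(t in batch for t in neighbors(g, s))
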