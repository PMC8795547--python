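"""Compiled Gillespie engine for 2D/3D open-boundary lattice targets.

Clusters are occupancy vectors over the S target sites; ``B[c, s]`` counts
the occupied neighbours of site ``s`` in cluster ``c`` (= bond count ``n``
for members, frontier bond count ``b`` for vacancies).  Per-site Fenwick
trees over cluster slots make frontier sampling O(log maxC) per event:
``fen[s]`` carries weight ``b`` for clusters in which ``s`` is a frontier
vacancy, so the attachment total is ``nu/V * sum_s active[s] * W[s]`` with
``W[s]`` the tree total.

Detachment is restricted to singly-bonded members (leaves, which can never
disconnect a cluster).  At the binding energies where the reversible
scenario operates (E_B of order 25 k_BT and above) the n >= 2 Arrhenius
rates are suppressed by factors e^(-E_B) < 1e-10 relative to delta_1 and
contribute no events on any simulated horizon; the pure-Python reference
engine implements the full non-articulation detachment rule and serves as
the equivalence oracle at moderate binding energies.

Supports reversible binding, dimerization control and just-in-sequence
batches; activation influx windows run on the reference engine.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .kinetics import Trajectory, _supply_plan


@njit(cache=True)
def _lattice_core(
    S, V, mu, nu, delta1,
    deg, nbr, bi, bj,
    active, bt, bs, bc,
    maxC, target_completed, n_ref, stop_at_target,
    max_time, max_events, seed, ckpt_every,
    rec_t, rec_y, rec_c, rec_f, rec_n,
):
    np.random.seed(seed)
    nb_pairs = bi.shape[0]
    occ = np.zeros((maxC, S), dtype=np.uint8)
    B = np.zeros((maxC, S), dtype=np.int16)
    size = np.zeros(maxC, dtype=np.int64)
    leaf = np.zeros(maxC, dtype=np.int64)
    W = np.zeros(S, dtype=np.int64)
    fen = np.zeros((S, maxC + 1), dtype=np.int64)  # frontier b per (site, cluster)
    fend = np.zeros(maxC + 1, dtype=np.int64)  # leaf counts per cluster
    free_ids = np.empty(maxC, dtype=np.int64)
    for i in range(maxC):
        free_ids[i] = maxC - 1 - i
    n_free = maxC
    sc = np.zeros(4, dtype=np.int64)  # Adim, Aatt, leafsum, free_total
    cnt = np.zeros(4, dtype=np.int64)  # dimerize, attach, detach, influx
    rec_cap = rec_t.shape[0]

    def fen_update(s, c, d):
        i = c + 1
        while i <= maxC:
            fen[s, i] += d
            i += i & (-i)

    def fen_select(s, r):
        idx = 0
        bit = 1
        while (bit << 1) <= maxC:
            bit <<= 1
        rem = r
        while bit > 0:
            nxt = idx + bit
            if nxt <= maxC and fen[s, nxt] <= rem:
                rem -= fen[s, nxt]
                idx = nxt
            bit >>= 1
        return idx

    def fend_update(c, d):
        i = c + 1
        while i <= maxC:
            fend[i] += d
            i += i & (-i)

    def fend_select(r):
        idx = 0
        bit = 1
        while (bit << 1) <= maxC:
            bit <<= 1
        rem = r
        while bit > 0:
            nxt = idx + bit
            if nxt <= maxC and fend[nxt] <= rem:
                rem -= fend[nxt]
                idx = nxt
            bit >>= 1
        return idx

    def frontier_change(s, c, d):
        # site s is a vacancy of cluster c whose weight changes by d
        fen_update(s, c, d)
        W[s] += d
        sc[1] += active[s] * d

    def active_change(s, d):
        sc[1] += d * W[s]
        acc = 0
        for q in range(deg[s]):
            acc += active[nbr[s, q]]
        sc[0] += d * acc
        active[s] += d
        sc[3] += d

    def leaf_change(c, d):
        leaf[c] += d
        sc[2] += d
        fend_update(c, d)

    def add_member(c, x):
        frontier_change(x, c, -B[c, x])
        occ[c, x] = 1
        size[c] += 1
        if B[c, x] == 1:
            leaf_change(c, 1)
        for q in range(deg[x]):
            t = nbr[x, q]
            B[c, t] += 1
            if occ[c, t] == 1:
                if B[c, t] == 2:
                    leaf_change(c, -1)
                elif B[c, t] == 1:
                    leaf_change(c, 1)
            else:
                frontier_change(t, c, 1)

    def remove_member(c, x):
        occ[c, x] = 0
        size[c] -= 1
        if B[c, x] == 1:
            leaf_change(c, -1)
        frontier_change(x, c, B[c, x])
        for q in range(deg[x]):
            t = nbr[x, q]
            B[c, t] -= 1
            if occ[c, t] == 1:
                if B[c, t] == 1:
                    leaf_change(c, 1)
                elif B[c, t] == 0:
                    leaf_change(c, -1)
            else:
                frontier_change(t, c, -1)

    # initial accumulators
    for p in range(nb_pairs):
        sc[0] += active[bi[p]] * active[bj[p]]
    sc[3] = active.sum()

    t = 0.0
    t90 = np.nan
    completed = 0
    last_rec_completed = 0
    n_events = 0
    bptr = 0
    censored = False

    rec_t[0] = 0.0
    rec_y[0] = 0.0
    rec_c[0] = 0
    rec_f[0] = sc[3]
    rec_n[0] = 0
    ridx = 1

    while True:
        if n_events >= max_events:
            censored = completed < target_completed
            break
        T_dim = mu * sc[0] / V
        T_att = nu * sc[1] / V
        T_det = delta1 * sc[2]
        nb = np.inf
        if bptr < bt.shape[0]:
            nb = bt[bptr]
        total = T_dim + T_att + T_det
        fired = False
        if total <= 0.0:
            if nb == np.inf:
                break
            t = nb
        else:
            dt = np.random.exponential() / total
            if t + dt >= nb:
                t = nb
            elif t + dt > max_time:
                t = max_time
                censored = completed < target_completed
                break
            else:
                t += dt
                fired = True
                u = np.random.random() * total
                if u < T_dim:
                    # --- dimerization ---
                    r = u * V / mu
                    p = 0
                    acc = 0.0
                    for pp in range(nb_pairs):
                        w = active[bi[pp]] * active[bj[pp]]
                        if w > 0:
                            p = pp
                            acc += w
                            if r < acc:
                                break
                    if n_free == 0:
                        censored = completed < target_completed
                        break
                    c = free_ids[n_free - 1]
                    n_free -= 1
                    add_member(c, bi[p])
                    add_member(c, bj[p])
                    active_change(bi[p], -1)
                    active_change(bj[p], -1)
                    cnt[0] += 1
                elif u < T_dim + T_att:
                    # --- attachment ---
                    r = (u - T_dim) * V / nu
                    s = 0
                    accb = 0.0
                    for ss in range(S):
                        w = active[ss] * W[ss]
                        if w > 0:
                            s = ss
                            if r < accb + w:
                                r -= accb
                                break
                            accb += w
                    c = fen_select(s, r / active[s])
                    if c >= maxC or occ[c, s] == 1 or B[c, s] == 0:
                        # float-edge guard: fall back to any frontier holder
                        c = -1
                        for cc in range(maxC):
                            if occ[cc, s] == 0 and B[cc, s] > 0 and size[cc] > 0:
                                c = cc
                                break
                    if c >= 0:
                        add_member(c, s)
                        active_change(s, -1)
                        cnt[1] += 1
                        if size[c] == S:
                            completed += 1
                            # clear the completed (absorbing) structure
                            leaf_change(c, -leaf[c])
                            for s2 in range(S):
                                occ[c, s2] = 0
                                B[c, s2] = 0
                            size[c] = 0
                            free_ids[n_free] = c
                            n_free += 1
                else:
                    # --- detachment of a leaf member ---
                    r = (u - T_dim - T_att) / delta1
                    c = fend_select(r)
                    if c >= maxC or leaf[c] == 0:
                        c = -1
                        for cc in range(maxC):
                            if leaf[cc] > 0:
                                c = cc
                                break
                    if c >= 0:
                        # pick the j-th leaf member uniformly
                        j = int(np.random.random() * leaf[c])
                        if j >= leaf[c]:
                            j = leaf[c] - 1
                        x = -1
                        seen = 0
                        for ss in range(S):
                            if occ[c, ss] == 1 and B[c, ss] == 1:
                                if seen == j:
                                    x = ss
                                    break
                                seen += 1
                        if x >= 0:
                            remove_member(c, x)
                            active_change(x, 1)
                            cnt[2] += 1
                            if size[c] == 1:
                                for ss in range(S):
                                    if occ[c, ss] == 1:
                                        remove_member(c, ss)
                                        active_change(ss, 1)
                                        break
                            if size[c] == 0:
                                free_ids[n_free] = c
                                n_free += 1
                n_events += 1
                want_rec = completed != last_rec_completed or (
                    ckpt_every > 0 and n_events % ckpt_every == 0
                )
                if want_rec and ridx < rec_cap:
                    rec_t[ridx] = t
                    rec_y[ridx] = completed / n_ref
                    rec_c[ridx] = maxC - n_free
                    rec_f[ridx] = sc[3]
                    rec_n[ridx] = completed
                    ridx += 1
                    last_rec_completed = completed
                if completed >= target_completed and np.isnan(t90):
                    t90 = t
                    if stop_at_target:
                        break
        if not fired:
            while bptr < bt.shape[0] and bt[bptr] <= t:
                active_change(bs[bptr] - 1, bc[bptr])
                bptr += 1
            if t >= max_time:
                censored = completed < target_completed
                break

    if ridx < rec_cap:
        rec_t[ridx] = t
        rec_y[ridx] = completed / n_ref
        rec_c[ridx] = maxC - n_free
        rec_f[ridx] = sc[3]
        rec_n[ridx] = completed
        ridx += 1
    return (
        t, t90, completed, n_events, cnt[0], cnt[1], cnt[2],
        ridx, censored, active, occ, size,
    )


def run_lattice(
    config, target_completed, max_time, max_events, seed,
    run_until, checkpoint_every,
) -> Trajectory:
    """Run one realization on the compiled 2D/3D lattice engine."""
    geometry = config.geometry
    rates = config.rates
    if geometry.d < 2:
        raise ValueError("lattice engine requires d >= 2 (use the ring engine)")
    if not np.isinf(rates.alpha):
        raise ValueError("influx windows are not supported by the lattice engine")
    S = geometry.S
    active0, unsup0, bt, bs, bc, ws, we, wr = _supply_plan(config)
    maxdeg = max(len(a) for a in geometry.adjacency)
    deg = np.array([len(a) for a in geometry.adjacency], dtype=np.int64)
    nbr = np.zeros((S, maxdeg), dtype=np.int64)
    for s, adj in enumerate(geometry.adjacency):
        for q, t_ in enumerate(adj):
            nbr[s, q] = t_ - 1
    pairs = geometry.bond_pairs()
    bi = np.array([i - 1 for i, _ in pairs], dtype=np.int64)
    bj = np.array([j - 1 for _, j in pairs], dtype=np.int64)
    total_monomers = int(active0.sum() + bc.sum())
    maxC = max(total_monomers // 2 + 2, 4)
    n_ref = config.n_ref
    rec_cap = 10_000 + 4 * n_ref + 64
    rec_t = np.zeros(rec_cap)
    rec_y = np.zeros(rec_cap)
    rec_c = np.zeros(rec_cap, dtype=np.int64)
    rec_f = np.zeros(rec_cap, dtype=np.int64)
    rec_n = np.zeros(rec_cap, dtype=np.int64)
    (
        t, t90, completed, n_events, c_dim, c_att, c_det,
        ridx, censored, active, occ, size,
    ) = _lattice_core(
        S, rates.V, rates.mu, rates.nu, rates.delta1,
        deg, nbr, bi, bj,
        active0.copy(), bt, bs, bc,
        maxC, target_completed, n_ref, run_until == "target",
        float(max_time), max_events, int(seed) & 0x7FFFFFFF,
        int(checkpoint_every), rec_t, rec_y, rec_c, rec_f, rec_n,
    )
    return Trajectory(
        times=rec_t[:ridx].copy(),
        yields=rec_y[:ridx].copy(),
        n_clusters=rec_c[:ridx].copy(),
        free_monomers=rec_f[:ridx].copy(),
        completed=rec_n[:ridx].copy(),
        t90=float(t90),
        censored=bool(censored),
        final_time=float(t),
        final_yield=completed / n_ref,
        n_ref=n_ref,
        n_events=int(n_events),
        event_counts={
            "dimerize": int(c_dim),
            "attach": int(c_att),
            "detach": int(c_det),
            "influx": 0,
        },
        seed=int(seed),
        final_state=(np.asarray(active), np.asarray(occ), np.asarray(size), int(completed)),
    )
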