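"""Compiled Gillespie engine for 1D ring targets.

Exploits the ring topology: every cluster is a contiguous arc, identified by
its starting species ``a`` (0-based) and length ``k``, so the whole cluster
population is a counts matrix ``M[a, k]``.  All clusters of an arc class are
interchangeable, which makes the propensity totals exact integer
accumulators:

* dimerization weight  ``Adim = sum_i active[i] * active[i+1]`` (ring pairs);
* attachment weight    ``Aatt = sum_s active[s] * (cntL[s] + cntR[s])`` where
  ``cntL/cntR`` count clusters whose left/right frontier vacancy is species
  ``s`` (the ring-closing arc ``k = S-1`` has both vacancies at the same
  site, reproducing the ``b = 2`` per-bond propensity automatically);
* detachment total     ``2 * delta1 * n_clusters`` (each incomplete arc has
  exactly its two singly-bonded ends removable).

Supports all four scenarios: instantaneous batches (JIS), per-species influx
windows (activation), reversible end detachment, and nucleation control.
Observationally equivalent to the pure-Python reference loop in
:mod:`selfassembly.kinetics`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .kinetics import Trajectory, _supply_plan


@njit(cache=True)
def _ring_core(
    S, V, mu, nu, delta1,
    active, unsup, bt, bs, bc, ws, we, wr, has_windows,
    target_completed, n_ref, stop_at_target, max_time, max_events, seed,
    ckpt_every, rec_t, rec_y, rec_c, rec_f, rec_n,
):
    np.random.seed(seed)
    M = np.zeros((S, S), dtype=np.int64)  # M[a, k]: arcs starting at a, length k
    Mrow = np.zeros(S, dtype=np.int64)
    cntR = np.zeros(S, dtype=np.int64)  # clusters whose right vacancy is species s
    sc = np.zeros(4, dtype=np.int64)  # Adim, Aatt, n_clusters, free_total
    cnt = np.zeros(4, dtype=np.int64)  # dimerize, attach, detach, influx
    rec_cap = rec_t.shape[0]

    def active_change(s, d):
        sc[1] += d * (Mrow[(s + 1) % S] + cntR[s])
        if S == 2:
            sc[0] += d * active[1 - s]
        else:
            sc[0] += d * (active[(s - 1) % S] + active[(s + 1) % S])
        active[s] += d
        sc[3] += d

    def cluster_change(a, k, d):
        M[a, k] += d
        Mrow[a] += d
        sc[2] += d
        lv = (a - 1) % S
        rv = (a + k) % S
        cntR[rv] += d
        sc[1] += d * (active[lv] + active[rv])

    # initial pools are already in `active`; build the accumulators directly
    if S == 2:
        sc[0] = active[0] * active[1]
    else:
        for s in range(S):
            sc[0] += active[s] * active[(s + 1) % S]
    sc[1] = 0  # no clusters yet
    sc[3] = active.sum()

    t = 0.0
    t90 = np.nan
    completed = 0
    last_rec_completed = -1
    n_events = 0
    bptr = 0
    ridx = 0
    censored = False

    rec_t[0] = 0.0
    rec_y[0] = 0.0
    rec_c[0] = 0
    rec_f[0] = sc[3]
    rec_n[0] = 0
    ridx = 1
    last_rec_completed = 0

    while True:
        if n_events >= max_events:
            censored = completed < target_completed
            break
        T_dim = mu * sc[0] / V
        T_att = nu * sc[1] / V
        T_det = 2.0 * delta1 * sc[2]
        T_inf = 0.0
        nb = np.inf
        if bptr < bt.shape[0]:
            nb = bt[bptr]
        if has_windows:
            for s in range(S):
                if unsup[s] > 0:
                    if ws[s] > t:
                        if ws[s] < nb:
                            nb = ws[s]
                    else:
                        T_inf += wr[s]
                        if we[s] < nb:
                            nb = we[s]
        total = T_dim + T_att + T_det + T_inf
        fired = False
        if total <= 0.0:
            if nb == np.inf:
                break  # globally absorbing
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
                    i = 0
                    if S > 2:
                        r = u * V / mu
                        acc = 0.0
                        for ii in range(S):
                            w = active[ii] * active[(ii + 1) % S]
                            if w > 0:
                                i = ii
                                acc += w
                                if r < acc:
                                    break
                    j = (i + 1) % S
                    active_change(i, -1)
                    active_change(j, -1)
                    cnt[0] += 1
                    if S == 2:
                        completed += 1
                    else:
                        cluster_change(i, 2, 1)
                elif u < T_dim + T_att:
                    # --- attachment ---
                    r = (u - T_dim) * V / nu
                    s = 0
                    accb = 0.0
                    for ss in range(S):
                        w = active[ss] * (Mrow[(ss + 1) % S] + cntR[ss])
                        if w > 0:
                            s = ss
                            if r < accb + w:
                                r -= accb
                                break
                            accb += w
                    cL = Mrow[(s + 1) % S]
                    jdx = int(r / active[s])
                    if jdx >= cL + cntR[s]:
                        jdx = cL + cntR[s] - 1
                    if jdx < cL:
                        a = (s + 1) % S  # left attach: arc starts right of s
                        k = 2
                        acc2 = 0
                        for kk in range(2, S):
                            if M[a, kk] > 0:
                                k = kk
                            acc2 += M[a, kk]
                            if jdx < acc2:
                                k = kk
                                break
                    else:
                        jdx -= cL
                        a = 0
                        k = 2
                        acc2 = 0
                        for kk in range(2, S):
                            aa = (s - kk) % S
                            if M[aa, kk] > 0:
                                a = aa
                                k = kk
                            acc2 += M[aa, kk]
                            if jdx < acc2:
                                a = aa
                                k = kk
                                break
                    cluster_change(a, k, -1)
                    active_change(s, -1)
                    if k == S - 1:
                        completed += 1
                    elif (a + k) % S == s:  # right attach keeps start a
                        cluster_change(a, k + 1, 1)
                    else:  # left attach: new start is s
                        cluster_change(s, k + 1, 1)
                    cnt[1] += 1
                elif u < T_dim + T_att + T_det:
                    # --- detachment (arc ends, n = 1) ---
                    r = (u - T_dim - T_att) / (2.0 * delta1)
                    cidx = int(r)
                    if cidx >= sc[2]:
                        cidx = sc[2] - 1
                    left = (r - cidx) < 0.5
                    a = 0
                    k = 2
                    acc2 = 0
                    done = False
                    for aa in range(S):
                        if cidx < acc2 + Mrow[aa]:
                            for kk in range(2, S):
                                acc2 += M[aa, kk]
                                if cidx < acc2:
                                    a = aa
                                    k = kk
                                    done = True
                                    break
                            if done:
                                break
                        else:
                            acc2 += Mrow[aa]
                    if not done:  # float-edge guard: take any populated class
                        for aa in range(S):
                            if Mrow[aa] > 0:
                                for kk in range(2, S):
                                    if M[aa, kk] > 0:
                                        a = aa
                                        k = kk
                                        done = True
                                        break
                            if done:
                                break
                    cluster_change(a, k, -1)
                    if left:
                        active_change(a, 1)
                        if k == 2:
                            active_change((a + 1) % S, 1)
                        else:
                            cluster_change((a + 1) % S, k - 1, 1)
                    else:
                        active_change((a + k - 1) % S, 1)
                        if k == 2:
                            active_change(a, 1)
                        else:
                            cluster_change(a, k - 1, 1)
                    cnt[2] += 1
                else:
                    # --- influx (one activated copy) ---
                    r = u - T_dim - T_att - T_det
                    acc = 0.0
                    for ss in range(S):
                        if unsup[ss] > 0 and ws[ss] <= t < we[ss]:
                            acc += wr[ss]
                            if r < acc:
                                unsup[ss] -= 1
                                active_change(ss, 1)
                                break
                    cnt[3] += 1
                n_events += 1
                want_rec = completed != last_rec_completed or (
                    ckpt_every > 0 and n_events % ckpt_every == 0
                )
                if want_rec and ridx < rec_cap:
                    rec_t[ridx] = t
                    rec_y[ridx] = completed / n_ref
                    rec_c[ridx] = sc[2]
                    rec_f[ridx] = sc[3]
                    rec_n[ridx] = completed
                    ridx += 1
                    last_rec_completed = completed
                if completed >= target_completed and np.isnan(t90):
                    t90 = t
                    if stop_at_target:
                        break
        if not fired:
            # boundary reached: apply due batches and window flushes
            while bptr < bt.shape[0] and bt[bptr] <= t:
                active_change(bs[bptr] - 1, bc[bptr])
                bptr += 1
            if has_windows:
                for s in range(S):
                    if unsup[s] > 0 and t >= we[s]:
                        active_change(s, unsup[s])
                        unsup[s] = 0
            if t >= max_time:
                censored = completed < target_completed
                break

    if ridx < rec_cap:
        rec_t[ridx] = t
        rec_y[ridx] = completed / n_ref
        rec_c[ridx] = sc[2]
        rec_f[ridx] = sc[3]
        rec_n[ridx] = completed
        ridx += 1
    return (
        t, t90, completed, n_events, cnt[0], cnt[1], cnt[2], cnt[3],
        ridx, censored, active, unsup, M,
    )


def run_ring(
    config, target_completed, max_time, max_events, seed,
    run_until, checkpoint_every,
) -> Trajectory:
    """Run one realization on the compiled ring engine."""
    geometry = config.geometry
    rates = config.rates
    if geometry.d != 1:
        raise ValueError("ring engine requires a 1D geometry")
    active0, unsup0, bt, bs, bc, ws, we, wr = _supply_plan(config)
    has_windows = bool(np.any(wr > 0))
    n_ref = config.n_ref
    rec_cap = 10_000 + 4 * n_ref + 64
    rec_t = np.zeros(rec_cap)
    rec_y = np.zeros(rec_cap)
    rec_c = np.zeros(rec_cap, dtype=np.int64)
    rec_f = np.zeros(rec_cap, dtype=np.int64)
    rec_n = np.zeros(rec_cap, dtype=np.int64)
    (
        t, t90, completed, n_events, c_dim, c_att, c_det, c_inf,
        ridx, censored, active, unsup, M,
    ) = _ring_core(
        geometry.S, rates.V, rates.mu, rates.nu, rates.delta1,
        active0.copy(), unsup0.copy(), bt, bs, bc, ws, we, wr, has_windows,
        target_completed, n_ref, run_until == "target",
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
            "influx": int(c_inf),
        },
        seed=int(seed),
        final_state=(np.asarray(active), np.asarray(unsup), np.asarray(M), int(completed)),
    )
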