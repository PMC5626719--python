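"""Numba inner loops for the annealed partition search.

The state carried through a run is (calls, O, R, z): the per-individual
call codes, the per-locus group x allele count tables, their row totals
and the 0-based assignment vector.  All LR arithmetic goes through a
precomputed ``xl[c] = c*ln(c)`` table, using the decomposition of the
per-locus LR into ``sum xlogx(O) - sum_rows xlogx(R) + const`` (allele
marginals never change when individuals move, so the constant cancels in
every delta).

Kernels mutate their arguments in place and are deterministic: all
randomness enters through pre-drawn ``r_seq``/``u_seq`` arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MISSING = -1


@njit(cache=True)
def _move_deltas(calls, r, O, R, xl, a, delta):
    """delta[c] = LR change if individual r moves from row a to row c."""
    S = O.shape[0]
    K = O.shape[1]
    P = calls.shape[2]
    for c in range(K):
        delta[c] = 0.0
    for s in range(S):
        m = 0
        for p in range(P):
            if calls[r, s, p] != MISSING:
                m += 1
        if m == 0:
            continue
        # removal from row a (identical for every destination)
        rem = 0.0
        for p in range(P):
            al = calls[r, s, p]
            if al == MISSING:
                continue
            dup = 0
            for q in range(p):
                if calls[r, s, q] == al:
                    dup += 1
            o = O[s, a, al] - dup
            rem += xl[o - 1] - xl[o]
        Ra = R[s, a]
        rem -= xl[Ra - m] - xl[Ra]
        for c in range(K):
            if c == a:
                continue
            add = 0.0
            for p in range(P):
                al = calls[r, s, p]
                if al == MISSING:
                    continue
                dup = 0
                for q in range(p):
                    if calls[r, s, q] == al:
                        dup += 1
                o = O[s, c, al] + dup
                add += xl[o + 1] - xl[o]
            Rc = R[s, c]
            add -= xl[Rc + m] - xl[Rc]
            delta[c] += rem + add


@njit(cache=True)
def _apply(calls, r, O, R, a, c):
    S = O.shape[0]
    P = calls.shape[2]
    for s in range(S):
        for p in range(P):
            al = calls[r, s, p]
            if al == MISSING:
                continue
            O[s, a, al] -= 1
            O[s, c, al] += 1
            R[s, a] -= 1
            R[s, c] += 1


@njit(cache=True)
def anneal_chain(calls, O, R, xl, z, r_seq, u_seq, t_seq, steps_per_epoch, lr0, z_best, trace):
    """Annealed Gibbs sweep; returns (lr_best, lr_final).

    One step resamples the label of individual ``r_seq[t]`` from
    p(C) proportional to exp(LR(move to C)/T) in max-subtracted form.
    ``trace[e]`` records the best LR seen up to the end of epoch ``e``.
    """
    K = O.shape[1]
    n_steps = r_seq.shape[0]
    delta = np.empty(K, dtype=np.float64)
    w = np.empty(K, dtype=np.float64)
    lr_cur = lr0
    lr_best = lr0
    for i in range(z.shape[0]):
        z_best[i] = z[i]
    epoch = 0
    for t in range(n_steps):
        r = r_seq[t]
        a = z[r]
        _move_deltas(calls, r, O, R, xl, a, delta)
        T = t_seq[t]
        mx = delta[0]
        for c in range(1, K):
            if delta[c] > mx:
                mx = delta[c]
        tot = 0.0
        for c in range(K):
            w[c] = np.exp((delta[c] - mx) / T)
            tot += w[c]
        u = u_seq[t] * tot
        chosen = K - 1
        acc = 0.0
        for c in range(K):
            acc += w[c]
            if u < acc:
                chosen = c
                break
        if chosen != a:
            _apply(calls, r, O, R, a, chosen)
            z[r] = chosen
            lr_cur += delta[chosen]
            if lr_cur > lr_best:
                lr_best = lr_cur
                for i in range(z.shape[0]):
                    z_best[i] = z[i]
        if (t + 1) % steps_per_epoch == 0:
            trace[epoch] = lr_best
            epoch += 1
    return lr_best, lr_cur


@njit(cache=True)
def greedy_passes(calls, O, R, xl, z, max_passes, lr0, tol):
    """Zero-temperature refinement: move each individual to its argmax group.

    Ties keep the current label; among strictly better destinations the
    smallest label wins.  Stops after a full pass with no move.  Returns
    (lr_final, n_passes_used); LR never decreases.
    """
    N = z.shape[0]
    K = O.shape[1]
    delta = np.empty(K, dtype=np.float64)
    lr_cur = lr0
    for p in range(max_passes):
        moved = 0
        for r in range(N):
            a = z[r]
            _move_deltas(calls, r, O, R, xl, a, delta)
            best_c = a
            best_d = tol
            for c in range(K):
                if c != a and delta[c] > best_d:
                    best_d = delta[c]
                    best_c = c
            if best_c != a:
                _apply(calls, r, O, R, a, best_c)
                z[r] = best_c
                lr_cur += delta[best_c]
                moved += 1
        if moved == 0:
            return lr_cur, p + 1
    return lr_cur, max_passes
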