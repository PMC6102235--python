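"""Numba-compiled inner loops: the synchronous lattice sweep and Margolus mixing.

State codes: 0 = S (susceptible), 1 = I (infected), 2 = R (recovered).

Timers are stored as integer sweep counts (elapsed time = count * dt) so the
deterministic residence times tau_I and tau_R are honoured exactly, with no
drift from repeated floating-point accumulation of dt.

All stochastic decisions taken inside these kernels draw from numba's global
per-process RNG, seeded through :func:`seed_rng`.
"""

import numpy as np
from numba import njit

S_STATE = 0
I_STATE = 1
R_STATE = 2

# absorbs representation error of tau values that are multiples of dt
_TOL = 1e-9


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def sweep(state, timer, beta, tau,
          new_state, new_timer, new_beta, new_tau,
          nbr_r, nbr_c,
          dt, tau_r, mu, d_beta, d_tau, per_trait_mutation,
          p_long, exact_source,
          record, t_event, last_inf, int_sum, int_sum2, int_cnt):
    """One synchronous update of the whole lattice.

    Reads only the old arrays (state, timer, beta, tau) and writes every site
    of the new arrays, so within-sweep ordering cannot leak information.
    Returns the number of infected sites after the sweep.
    """
    nr, nc = state.shape
    cand_b = np.empty(8, np.float64)
    cand_i = np.empty(8, np.int64)
    cand_j = np.empty(8, np.int64)
    n_inf = 0
    for i in range(nr):
        for j in range(nc):
            st = state[i, j]
            if st == S_STATE:
                m = 0
                total = 0.0
                for k in range(8):
                    ri = nbr_r[i, j, k]
                    rj = nbr_c[i, j, k]
                    if p_long > 0.0 and np.random.random() < p_long:
                        ri = np.random.randint(0, nr)
                        rj = np.random.randint(0, nc)
                        while ri == i and rj == j:
                            ri = np.random.randint(0, nr)
                            rj = np.random.randint(0, nc)
                    if state[ri, rj] == I_STATE:
                        cand_b[m] = beta[ri, rj]
                        cand_i[m] = ri
                        cand_j[m] = rj
                        total += beta[ri, rj]
                        m += 1
                infected = False
                if m > 0:
                    p = 1.0 - np.exp(-dt * total)
                    if np.random.random() < p:
                        if exact_source:
                            wsum = 0.0
                            for k in range(m):
                                wsum += 1.0 - np.exp(-dt * cand_b[k])
                            u = np.random.random() * wsum
                        else:
                            u = np.random.random() * total
                        acc = 0.0
                        src = m - 1
                        for k in range(m):
                            if exact_source:
                                acc += 1.0 - np.exp(-dt * cand_b[k])
                            else:
                                acc += cand_b[k]
                            if u < acc:
                                src = k
                                break
                        si = cand_i[src]
                        sj = cand_j[src]
                        new_state[i, j] = I_STATE
                        new_timer[i, j] = 0
                        new_beta[i, j] = beta[si, sj]
                        new_tau[i, j] = tau[si, sj]
                        infected = True
                        n_inf += 1
                        if record:
                            if last_inf[i, j] >= 0.0:
                                iv = t_event - last_inf[i, j]
                                int_sum[i, j] += iv
                                int_sum2[i, j] += iv * iv
                                int_cnt[i, j] += 1
                            last_inf[i, j] = t_event
                if not infected:
                    new_state[i, j] = S_STATE
                    new_timer[i, j] = timer[i, j] + 1
                    new_beta[i, j] = 0.0
                    new_tau[i, j] = 0.0
            elif st == I_STATE:
                if timer[i, j] * dt >= tau[i, j] - _TOL:
                    new_state[i, j] = R_STATE
                    new_timer[i, j] = 0
                    new_beta[i, j] = 0.0
                    new_tau[i, j] = 0.0
                else:
                    b = beta[i, j]
                    t = tau[i, j]
                    if mu > 0.0:
                        if per_trait_mutation:
                            if np.random.random() < mu * dt:
                                nb = b + d_beta if np.random.random() < 0.5 else b - d_beta
                                if nb > 0.0:
                                    b = nb
                            if np.random.random() < mu * dt:
                                nt = t + d_tau if np.random.random() < 0.5 else t - d_tau
                                if nt > 0.0:
                                    t = nt
                        elif np.random.random() < mu * dt:
                            nb = b + d_beta if np.random.random() < 0.5 else b - d_beta
                            if nb > 0.0:
                                b = nb
                            nt = t + d_tau if np.random.random() < 0.5 else t - d_tau
                            if nt > 0.0:
                                t = nt
                    new_state[i, j] = I_STATE
                    new_timer[i, j] = timer[i, j] + 1
                    new_beta[i, j] = b
                    new_tau[i, j] = t
                    n_inf += 1
            else:
                if timer[i, j] * dt >= tau_r - _TOL:
                    new_state[i, j] = S_STATE
                    new_timer[i, j] = 0
                else:
                    new_state[i, j] = R_STATE
                    new_timer[i, j] = timer[i, j] + 1
                new_beta[i, j] = 0.0
                new_tau[i, j] = 0.0
    return n_inf


@njit(cache=True)
def _rot4(a, i0, j0, i1, j1, cw):
    # corners: TL=(i0,j0)  TR=(i0,j1)  BR=(i1,j1)  BL=(i1,j0)
    if cw:
        t = a[i0, j1]
        a[i0, j1] = a[i0, j0]
        a[i0, j0] = a[i1, j0]
        a[i1, j0] = a[i1, j1]
        a[i1, j1] = t
    else:
        t = a[i0, j0]
        a[i0, j0] = a[i0, j1]
        a[i0, j1] = a[i1, j1]
        a[i1, j1] = a[i1, j0]
        a[i1, j0] = t


@njit(cache=True)
def margolus(state, timer, beta, tau, offset):
    """Rotate every 2x2 block a quarter turn, each in a random direction.

    Blocks are anchored at (offset, offset) with periodic wrap; offset is 0 or
    1 and alternates between successive applications.  The full site payload
    (state, timer, strain) moves together, so this is a pure permutation.
    """
    nr, nc = state.shape
    for bi in range(0, nr, 2):
        for bj in range(0, nc, 2):
            i0 = (bi + offset) % nr
            j0 = (bj + offset) % nc
            i1 = (i0 + 1) % nr
            j1 = (j0 + 1) % nc
            cw = np.random.random() < 0.5
            _rot4(state, i0, j0, i1, j1, cw)
            _rot4(timer, i0, j0, i1, j1, cw)
            _rot4(beta, i0, j0, i1, j1, cw)
            _rot4(tau, i0, j0, i1, j1, cw)
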