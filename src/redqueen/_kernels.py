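"""Compiled (numba) inner loops for the stochastic simulations.

These kernels mirror, reaction for reaction, the rate definitions built
by :mod:`redqueen.reaction_systems` (the Python `Reaction` closures are
the reference path; tests assert both paths agree on random states).
Stoichiometry is passed in from the Python `ReactionSystem`, so only the
rate arithmetic is duplicated here.

Status codes returned by the drivers:

====  =========================================
0     a genotype count hit zero (first loss)
1     time cap ``t_max`` reached (censored)
2     event-count cap reached (censored)
3     total-population cap reached (censored)
4     absorbed: all reaction rates are zero
====  =========================================
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_LOSS = 0
STATUS_T_MAX = 1
STATUS_EVENT_MAX = 2
STATUS_N_MAX = 3
STATUS_ABSORBED = 4

# params vector layout (ModelParams.kernel_vector):
# [w_H, w_P, alpha, beta, b_H, d_P, lam, comp_rate, mut_H, mut_P]


@njit(cache=True)
def fill_rates(code, H, P, par, with_mut, rates):
    """Evaluate all reaction rates at the current state; returns the count."""
    n = H.shape[0]
    wH, wP, alpha, beta = par[0], par[1], par[2], par[3]
    bH, dP, lam, comp = par[4], par[5], par[6], par[7]
    mutH, mutP = par[8], par[9]
    NH = 0
    NP = 0
    for i in range(n):
        NH += H[i]
        NP += P[i]

    m = 0
    if code == 1 or code == 2:  # EvoPlus / Evo, n == 2
        for k in range(4):
            rates[k] = 0.0
        if NH > 0 and NP > 0:
            h1 = H[0] / NH
            h2 = H[1] / NH
            p1 = P[0] / NP
            p2 = P[1] / NP
            piH1 = (alpha + beta) - (alpha * p1 + beta * p2)
            piH2 = (alpha + beta) - (beta * p1 + alpha * p2)
            fH1 = 1.0 - wH + wH * piH1
            fH2 = 1.0 - wH + wH * piH2
            piP1 = alpha * h1 + beta * h2
            piP2 = beta * h1 + alpha * h2
            fP1 = 1.0 - wP + wP * piP1
            fP2 = 1.0 - wP + wP * piP2
            prodH = h1 * h2
            prodP = p1 * p2
            if code == 1:
                if prodH > 0.0:
                    fbar = h1 * fH1 + h2 * fH2
                    rates[0] = prodH * fH1 / fbar
                    rates[1] = prodH * fH2 / fbar
                if prodP > 0.0:
                    fbar = p1 * fP1 + p2 * fP2
                    rates[2] = prodP * fP1 / fbar
                    rates[3] = prodP * fP2 / fbar
            else:
                spanH = wH * (alpha - beta)
                gH = 0.5 if spanH == 0.0 else 0.5 + 0.5 * (fH1 - fH2) / spanH
                rates[0] = prodH * gH
                rates[1] = prodH * (1.0 - gH)
                spanP = wP * (alpha - beta)
                gP = 0.5 if spanP == 0.0 else 0.5 + 0.5 * (fP1 - fP2) / spanP
                rates[2] = prodP * gP
                rates[3] = prodP * (1.0 - gP)
        m = 4

    elif code == 3:  # Hybrid
        Dbar = 0.0
        Bbar = 0.0
        for i in range(n):
            mh = (beta * NP + (alpha - beta) * P[i]) / NP if NP > 0 else 0.0
            d_i = 1.0 - wH + wH * mh
            rates[i] = H[i] * d_i  # host death
            Dbar += H[i] * d_i
            mp = (beta * NH + (alpha - beta) * H[i]) / NH if NH > 0 else 0.0
            b_i = 1.0 - wP + wP * mp
            rates[2 * n + i] = P[i] * b_i  # parasite birth
            Bbar += P[i] * b_i
        for i in range(n):
            rates[n + i] = H[i] * Dbar / NH if NH > 0 else 0.0  # host birth
            rates[3 * n + i] = P[i] * Bbar / NP if NP > 0 else 0.0  # parasite death
        m = 4 * n

    else:  # EcoEvo (4) / EcoEvoPlus (5)
        for i in range(n):
            rates[i] = bH * H[i]  # host birth
            rates[n + i] = dP * P[i]  # parasite death
            rates[2 * n + i] = lam * H[i] * P[i]  # matched host death
            rates[3 * n + i] = lam * H[i] * P[i]  # matched parasite birth
        m = 4 * n
        if code == 5:
            for i in range(n):
                rates[m + i] = comp * H[i] * NH  # competition death
            m += n

    if with_mut:
        for i in range(n):
            rates[m + i] = 0.5 * mutH * H[i]  # H_i -> H_{i+1}
            rates[m + n + i] = 0.5 * mutH * H[i]  # H_i -> H_{i-1}
            rates[m + 2 * n + i] = 0.5 * mutP * P[i]
            rates[m + 3 * n + i] = 0.5 * mutP * P[i]
        m += 4 * n
    return m


@njit(cache=True)
def ssa_run(
    code,
    H,
    P,
    par,
    with_mut,
    delta_H,
    delta_P,
    t0,
    t_max,
    event_max,
    n_max,
    stop_on_loss,
    grid,
    rec_H,
    rec_P,
    rev_cap,
    rev_t,
    rev_sp,
    rev_g,
    seed,
):
    """Direct-method Gillespie driver.

    Mutates ``H``/``P`` in place; records the state holding at each grid
    time into ``rec_H``/``rec_P``; logs genotype revivals (a count
    leaving zero) into the ``rev_*`` buffers.  Returns
    ``(status, t, ext_species, ext_genotype, n_events, n_recorded,
    n_revivals)`` with species 0 = host, 1 = parasite.
    """
    np.random.seed(seed)
    n = H.shape[0]
    mr = delta_H.shape[0]
    rates = np.empty(mr)
    t = t0
    gi = 0
    ng = grid.shape[0]
    n_events = 0
    n_rev = 0

    if stop_on_loss:
        for i in range(n):
            if H[i] == 0:
                return (STATUS_LOSS, t, 0, i, n_events, gi, n_rev)
        for i in range(n):
            if P[i] == 0:
                return (STATUS_LOSS, t, 1, i, n_events, gi, n_rev)

    while True:
        m = fill_rates(code, H, P, par, with_mut, rates)
        total = 0.0
        for k in range(m):
            total += rates[k]
        if total <= 0.0:
            while gi < ng:
                for i in range(n):
                    rec_H[gi, i] = H[i]
                    rec_P[gi, i] = P[i]
                gi += 1
            return (STATUS_ABSORBED, t, -1, -1, n_events, gi, n_rev)

        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        tn = t - np.log(u) / total
        if tn > t_max:
            while gi < ng:
                for i in range(n):
                    rec_H[gi, i] = H[i]
                    rec_P[gi, i] = P[i]
                gi += 1
            return (STATUS_T_MAX, t_max, -1, -1, n_events, gi, n_rev)

        while gi < ng and grid[gi] < tn:
            for i in range(n):
                rec_H[gi, i] = H[i]
                rec_P[gi, i] = P[i]
            gi += 1

        r = np.random.random() * total
        k = 0
        acc = rates[0]
        while acc < r and k < m - 1:
            k += 1
            acc += rates[k]

        lost_sp = -1
        lost_g = -1
        for i in range(n):
            d = delta_H[k, i]
            if d != 0:
                if H[i] == 0 and d > 0 and n_rev < rev_cap:
                    rev_t[n_rev] = tn
                    rev_sp[n_rev] = 0
                    rev_g[n_rev] = i
                    n_rev += 1
                H[i] += d
                if H[i] == 0:
                    lost_sp = 0
                    lost_g = i
            d = delta_P[k, i]
            if d != 0:
                if P[i] == 0 and d > 0 and n_rev < rev_cap:
                    rev_t[n_rev] = tn
                    rev_sp[n_rev] = 1
                    rev_g[n_rev] = i
                    n_rev += 1
                P[i] += d
                if P[i] == 0 and lost_sp < 0:
                    lost_sp = 1
                    lost_g = i

        t = tn
        n_events += 1
        if stop_on_loss and lost_sp >= 0:
            return (STATUS_LOSS, t, lost_sp, lost_g, n_events, gi, n_rev)
        if n_events >= event_max:
            return (STATUS_EVENT_MAX, t, -1, -1, n_events, gi, n_rev)
        NT = 0
        for i in range(n):
            NT += H[i] + P[i]
        if NT > n_max:
            return (STATUS_N_MAX, t, -1, -1, n_events, gi, n_rev)


@njit(cache=True)
def _dt_pair(moran, x1, opp1, w, alpha, beta, is_host):
    """One species' (+1, -1) step probabilities for genotype 1."""
    x2 = 1.0 - x1
    prod = x1 * x2
    if prod == 0.0:
        return 0.0, 0.0
    if is_host:
        pi1 = (alpha + beta) - (alpha * opp1 + beta * (1.0 - opp1))
        pi2 = (alpha + beta) - (beta * opp1 + alpha * (1.0 - opp1))
    else:
        pi1 = alpha * opp1 + beta * (1.0 - opp1)
        pi2 = beta * opp1 + alpha * (1.0 - opp1)
    f1 = 1.0 - w + w * pi1
    f2 = 1.0 - w + w * pi2
    if moran:
        fbar = x1 * f1 + x2 * f2
        return prod * f1 / fbar, prod * f2 / fbar
    span = w * (alpha - beta)
    g = 0.5 if span == 0.0 else 0.5 + 0.5 * (f1 - f2) / span
    return prod * g, prod * (1.0 - g)


@njit(cache=True)
def _dt_boundary(H1, NH, P1, NP):
    """(species, genotype) of a lost genotype, host checked first; (-1,-1) if none."""
    if H1 == 0:
        return 0, 0
    if H1 == NH:
        return 0, 1
    if P1 == 0:
        return 1, 0
    if P1 == NP:
        return 1, 1
    return -1, -1


@njit(cache=True)
def dt_run(moran, H1, NH, P1, NP, wH, wP, alpha, beta, max_steps, seed):
    """Discrete-time two-species run; both species update simultaneously.

    Returns ``(steps, species, genotype, censored)``; ``steps`` is the
    extinction time in paired-update steps.
    """
    np.random.seed(seed)
    step = 0
    while step < max_steps:
        sp, g = _dt_boundary(H1, NH, P1, NP)
        if sp >= 0:
            return (step, sp, g, 0)
        h1 = H1 / NH
        p1 = P1 / NP
        up_h, down_h = _dt_pair(moran, h1, p1, wH, alpha, beta, True)
        up_p, down_p = _dt_pair(moran, p1, h1, wP, alpha, beta, False)
        u = np.random.random()
        if u < up_h:
            H1 += 1
        elif u < up_h + down_h:
            H1 -= 1
        u = np.random.random()
        if u < up_p:
            P1 += 1
        elif u < up_p + down_p:
            P1 -= 1
        step += 1
    sp, g = _dt_boundary(H1, NH, P1, NP)
    if sp >= 0:
        return (step, sp, g, 0)
    return (step, -1, -1, 1)
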