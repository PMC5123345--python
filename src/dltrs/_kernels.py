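"""Numba kernels for the hot numerical paths.

These are deliberately plain-array functions: the slice ODE integrator for
extinction/propagation, the single-lineage propagation (p11) matrix builder,
the postorder gene-tree density dynamic programme, and the peeling
likelihood.  All state lives in the caller; kernels are pure.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def dlt_rhs(E, delta, mu, taueff):
    """Right-hand sides for extinction E and the p11 log-decay rate g.

    dE_e/dt = mu - (delta+mu+taueff) E_e + delta E_e^2
              + taueff/(k-1) * sum_{f != e} E_f E_e
    g_e     = (delta+mu+taueff) - 2 delta E_e - taueff/(k-1) sum_{f != e} E_f
    """
    k = E.shape[0]
    dE = np.empty(k)
    g = np.empty(k)
    S = 0.0
    for e in range(k):
        S += E[e]
    tot = delta + mu + taueff
    for e in range(k):
        trans = taueff / (k - 1) * (S - E[e]) if k > 1 else 0.0
        dE[e] = mu - tot * E[e] + delta * E[e] * E[e] + trans * E[e]
        g[e] = tot - 2.0 * delta * E[e] - trans
    return dE, g


@njit(cache=True)
def slice_integrate(E0, rel_times, delta, mu, tau, nsub):
    """Integrate one time slice bottom-up with fixed-step RK4.

    E0: extinction of each contemporaneous edge at the slice bottom.
    rel_times: recording times relative to the slice bottom (ascending,
    last one = slice height).  Returns extinction and the cumulative
    integral of g (the p11 exponent) at every recording time.
    """
    k = E0.shape[0]
    r = rel_times.shape[0]
    taueff = tau if k > 1 else 0.0
    E = E0.copy()
    C = np.zeros(k)
    outE = np.empty((r, k))
    outC = np.empty((r, k))
    t = 0.0
    for i in range(r):
        span = rel_times[i] - t
        h = span / nsub
        for _ in range(nsub):
            k1E, k1C = dlt_rhs(E, delta, mu, taueff)
            k2E, k2C = dlt_rhs(E + 0.5 * h * k1E, delta, mu, taueff)
            k3E, k3C = dlt_rhs(E + 0.5 * h * k2E, delta, mu, taueff)
            k4E, k4C = dlt_rhs(E + h * k3E, delta, mu, taueff)
            for e in range(k):
                E[e] += h / 6.0 * (k1E[e] + 2 * k2E[e] + 2 * k3E[e] + k4E[e])
                if E[e] < 0.0:
                    E[e] = 0.0
                elif E[e] > 1.0:
                    E[e] = 1.0
                C[e] += h / 6.0 * (k1C[e] + 2 * k2C[e] + 2 * k3C[e] + k4C[e])
        t = rel_times[i]
        for e in range(k):
            outE[i, e] = E[e]
            outC[i, e] = C[e]
    return outE, outC


@njit(cache=True)
def build_p11(order, kind, down, fac, spec_top, ext):
    """Dense p11 matrix between all grid points on a common descent path.

    P[i, j] is the probability that a single lineage at point i has exactly
    one surviving descendant located at point j with every side lineage
    spawned in between going extinct.  Within an edge consecutive points
    compose multiplicatively (fac); passing down through a speciation
    vertex multiplies by the sibling edge's extinction probability.
    """
    n = order.shape[0]
    P = np.zeros((n, n))
    for oi in range(n):
        i = order[oi]
        if kind[i] == 1:  # speciation vertex: branch into both child edges
            c1 = spec_top[i, 0]
            c2 = spec_top[i, 1]
            f1 = ext[c2]
            f2 = ext[c1]
            for j in range(n):
                P[i, j] = f1 * P[c1, j] + f2 * P[c2, j]
        elif down[i] >= 0:
            d = down[i]
            f = fac[i]
            for j in range(n):
                P[i, j] = f * P[d, j]
        P[i, i] = 1.0
    return P


@njit(cache=True)
def density_dp(
    P,
    pt_time,
    pt_delta,
    pt_kind,
    pt_tidx,
    spec_top,
    trans_off,
    trans_idx,
    stem_point,
    didx,
    rho,
    postorder,
    children,
    leaf_pt,
    root,
    delta,
    tau,
):
    """Postorder DP for the gene-tree density p(G, l | theta, S).

    s[u, x]: density that a lineage starting at grid point x evolves into
    the observed subtree of u, including the length of the edge above u.
    aD[u, y]: event density of u happening at y times the quadrature
    weight (speciation / duplication / symmetrised transfer terms).
    Both are max-normalised per gene vertex; sc_s / sc_a carry the log
    scales.  Returns (log density, s, aD, sc_s, sc_a).
    """
    ng = postorder.shape[0]
    n = P.shape[0]
    s = np.zeros((ng, n))
    aD = np.zeros((ng, n))
    sc_s = np.zeros(ng)
    sc_a = np.zeros(ng)

    for oi in range(ng):
        u = postorder[oi]
        c1 = children[u, 0]
        if c1 < 0:  # gene leaf anchored at its species leaf point
            lp = leaf_pt[u]
            tjy = pt_tidx[lp]
            for x in range(n):
                if x != lp and P[x, lp] > 0.0:
                    s[u, x] = P[x, lp] * rho[u, didx[pt_tidx[x], tjy]]
            m = 0.0
            for x in range(n):
                if s[u, x] > m:
                    m = s[u, x]
            if m > 0.0:
                for x in range(n):
                    s[u, x] /= m
                sc_s[u] = math.log(m)
            continue

        c2 = children[u, 1]
        base = sc_s[c1] + sc_s[c2]
        for y in range(n):
            kd = pt_kind[y]
            if kd == 1:  # speciation: children descend distinct child edges
                g1 = spec_top[y, 0]
                g2 = spec_top[y, 1]
                aD[u, y] = s[c1, g1] * s[c2, g2] + s[c1, g2] * s[c2, g1]
            elif kd == 4:  # interior event point
                val = 2.0 * delta * s[c1, y] * s[c2, y]
                lo = trans_off[y]
                hi = trans_off[y + 1]
                if hi > lo and tau > 0.0:
                    tsum = 0.0
                    for q in range(lo, hi):
                        yp = trans_idx[q]
                        tsum += s[c1, y] * s[c2, yp] + s[c1, yp] * s[c2, y]
                    val += tau / (hi - lo) * tsum
                aD[u, y] = pt_delta[y] * val
        ma = 0.0
        for y in range(n):
            if aD[u, y] > ma:
                ma = aD[u, y]
        if ma > 0.0:
            for y in range(n):
                aD[u, y] /= ma
            sc_a[u] = base + math.log(ma)
        else:
            sc_a[u] = base

        if u == root:
            continue
        for x in range(n):
            tix = pt_tidx[x]
            tx = pt_time[x]
            acc = 0.0
            for y in range(n):
                if P[x, y] > 0.0 and pt_time[y] < tx and aD[u, y] > 0.0:
                    acc += P[x, y] * rho[u, didx[tix, pt_tidx[y]]] * aD[u, y]
            s[u, x] = acc
        ms = 0.0
        for x in range(n):
            if s[u, x] > ms:
                ms = s[u, x]
        if ms > 0.0:
            for x in range(n):
                s[u, x] /= ms
            sc_s[u] = sc_a[u] + math.log(ms)
        else:
            sc_s[u] = sc_a[u]

    dens = 0.0
    for y in range(n):
        if aD[root, y] > 0.0:
            dens += P[stem_point, y] * aD[root, y]
    if dens <= 0.0:
        return NEG_INF, s, aD, sc_s, sc_a
    return math.log(dens) + sc_a[root], s, aD, sc_s, sc_a


@njit(cache=True)
def peeling(postorder, children, tprob, partials, weights, freqs, root):
    """Felsenstein peeling over compressed site patterns, with per-pattern
    rescaling.  tprob[v] is the transition matrix for the edge above vertex
    v.  partials holds leaf conditionals on entry and is overwritten for
    internal vertices.  Returns the total log likelihood.
    """
    ng = postorder.shape[0]
    npat = partials.shape[1]
    logscale = np.zeros(npat)
    for oi in range(ng):
        u = postorder[oi]
        c1 = children[u, 0]
        if c1 < 0:
            continue
        c2 = children[u, 1]
        for p in range(npat):
            mx = 0.0
            for b in range(4):
                left = 0.0
                right = 0.0
                for b2 in range(4):
                    left += tprob[c1, b, b2] * partials[c1, p, b2]
                    right += tprob[c2, b, b2] * partials[c2, p, b2]
                v = left * right
                partials[u, p, b] = v
                if v > mx:
                    mx = v
            if mx > 0.0 and mx < 1e-200:
                for b in range(4):
                    partials[u, p, b] /= mx
                logscale[p] += math.log(mx)
    total = 0.0
    for p in range(npat):
        site = 0.0
        for b in range(4):
            site += freqs[b] * partials[root, p, b]
        if site <= 0.0:
            return NEG_INF
        total += weights[p] * (math.log(site) + logscale[p])
    return total
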