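"""Independent brute-force oracles used to validate the implementation.

Every function here is written as a direct, unoptimized transcription of
the defining formula (loops, enumeration, or generic numerical
optimization) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def cindex_pairs(eta, time, event) -> float:
    """All-pairs enumeration of Harrell's c."""
    n = len(eta)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            )
            if not usable:
                continue
            den += 1
            if eta[i] > eta[j]:
                num += 1.0
            elif eta[i] == eta[j]:
                num += 0.5
    if den == 0:
        raise ZeroDivisionError("no usable pairs")
    return num / den


def pearson_matrix(X) -> np.ndarray:
    """Direct covariance/SD formula, pair by pair."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    out = np.empty((p, p))
    for a in range(p):
        for b in range(p):
            xa = X[:, a] - X[:, a].mean()
            xb = X[:, b] - X[:, b].mean()
            out[a, b] = (xa * xb).sum() / np.sqrt((xa**2).sum() * (xb**2).sum())
    return out


def holm_stepdown(pvals) -> np.ndarray:
    """Textbook Holm: sorted p * (m - rank + 1), cumulative max, cap 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


def breslow_neg_loglik(beta, X, time, event) -> float:
    """Breslow-ties Cox partial likelihood by direct risk-set summation."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = np.flatnonzero(time >= time[i])
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return -ll


def cox_fit_neldermead(X, time, event, lam: float = 0.0, l1: bool = False):
    """Generic numerical optimizer on the penalized partial likelihood."""
    X = np.atleast_2d(X)
    p = X.shape[1]

    def obj(b):
        pen = lam * np.abs(b).sum() if l1 else 0.5 * lam * (b**2).sum()
        return breslow_neg_loglik(b, X, time, event) + pen

    best = None
    for start in (np.zeros(p), 0.1 * np.ones(p)):
        res = minimize(obj, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def average_linkage_merges(D) -> list:
    """O(n^3) UPGMA agglomeration on a precomputed dissimilarity matrix;
    ties resolved toward the pair containing the smallest leaf indices.
    Returns [(a, b, height, size)] in scipy id convention."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    nid = n
    while len(clusters) > 1:
        best_pair, best_key = None, None
        for (a, b), d in dist.items():
            la, lb = min(clusters[a]), min(clusters[b])
            key = (d, min(la, lb), max(la, lb))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (a, b)
        a, b = best_pair
        d_ab = dist[(a, b)]
        new_members = clusters[a] + clusters[b]
        merges.append((a, b, d_ab, len(new_members)))
        for c in clusters:
            if c in (a, b):
                continue
            ka = (min(a, c), max(a, c))
            kb = (min(b, c), max(b, c))
            dist[(c, nid) if c < nid else (nid, c)] = (
                len(clusters[a]) * dist[ka] + len(clusters[b]) * dist[kb]
            ) / len(new_members)
        for c in list(clusters):
            dist.pop((min(a, c), max(a, c)), None)
            dist.pop((min(b, c), max(b, c)), None)
        del clusters[a], clusters[b]
        clusters[nid] = new_members
        nid += 1
    return merges


def km_survival(time, event):
    """Product-limit estimator by direct risk-set counting."""
    times = np.unique(time[event == 1])
    s = 1.0
    out = []
    for t in times:
        d = np.sum((time == t) & (event == 1))
        r = np.sum(time >= t)
        s *= 1 - d / r
        out.append((t, s))
    return out


def schemper_henderson_pev(eta, time, event) -> float:
    """Straight-line transcription of the explained-variation estimator.

    Subject-level absolute prediction errors at each distinct event time,
    for the Kaplan-Meier (null) and the Cox-model (eta) survival curves;
    event times weighted by d_t / G(t-) with G the censoring Kaplan-Meier.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.asarray(eta, float)
    n = len(time)
    ev_times = np.unique(time[event == 1])

    km = km_survival(time, event)

    def km_at(t):
        s = 1.0
        for tt, ss in km:
            if tt <= t:
                s = ss
        return s

    # Cox model on eta (standardized), fitted by generic optimization
    sd = eta.std()
    if sd == 0:
        cox_at = km_at_subject = None
    else:
        z = (eta - eta.mean()) / sd
        bhat = cox_fit_neldermead(z[:, None], time, event)[0]
        # Breslow baseline cumulative hazard
        def h0(t):
            tot = 0.0
            for tt in ev_times:
                if tt <= t:
                    d = np.sum((time == tt) & (event == 1))
                    tot += d / np.exp(z[time >= tt] * bhat).sum()
            return tot

        h0_cache = {tt: h0(tt) for tt in ev_times}

        def surv(i, t):
            tot = 0.0
            for tt in ev_times:
                if tt <= t:
                    tot = h0_cache[tt]
            return np.exp(-tot * np.exp(z[i] * bhat))

    # censoring KM, left-continuous
    cens_km = km_survival(time, 1 - event)

    def g_minus(t):
        s = 1.0
        for tt, ss in cens_km:
            if tt < t:
                s = ss
        return s

    def mean_error(surv_fn):
        total_w = 0.0
        acc = 0.0
        for tt in ev_times:
            d = np.sum((time == tt) & (event == 1))
            w = d / g_minus(tt)
            errs = []
            for i in range(n):
                s_t = surv_fn(i, tt)
                if time[i] > tt:
                    errs.append(1 - s_t)
                elif event[i] == 1:
                    errs.append(s_t)
                else:
                    s_c = surv_fn(i, time[i])
                    ratio = min(s_t / s_c, 1.0) if s_c > 0 else 0.0
                    errs.append(ratio * (1 - s_t) + (1 - ratio) * s_t)
            acc += w * np.mean(errs)
            total_w += w
        return acc / total_w

    D = mean_error(lambda i, t: km_at(t))
    if sd == 0:
        return 0.0
    Dx = mean_error(surv)
    return max((D - Dx) / D, 0.0)


def logrank_chi2(time, event, groups) -> float:
    """Two-or-more-group log-rank statistic by direct O-E/V summation
    (2-group form)."""
    labels = np.unique(groups)
    assert len(labels) == 2, "oracle handles the 2-group case"
    g = groups == labels[0]
    o_a = 0.0
    e_a = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n_tot = at_risk.sum()
        n_a = (at_risk & g).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & g).sum()
        o_a += d_a
        e_a += d * n_a / n_tot
        if n_tot > 1:
            v += d * (n_a / n_tot) * (1 - n_a / n_tot) * (n_tot - d) / (n_tot - 1)
    return (o_a - e_a) ** 2 / v
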