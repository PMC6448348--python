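"""Compiled kernel for the multivariate envelope mean.

This mirrors the pure-numpy path in :mod:`oscillosource.memd`
(`_project_envelopes` / `multivariate_mean`) exactly: projection onto
each direction, strict extrema with plateau midpoints, two-point edge
mirroring, natural cubic splines through every channel at the
projection extrema, and the average over directions.  The numpy path
remains the reference implementation; parity between the two is
asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _proj_extrema(p):
    """Strict local minima/maxima of a 1-D array; plateaus contribute
    their midpoint index."""
    T = p.shape[0]
    minima = np.empty(T, np.int64)
    maxima = np.empty(T, np.int64)
    nmin = 0
    nmax = 0
    prev_sign = 0
    prev_idx = -1
    for t in range(T - 1):
        d = p[t + 1] - p[t]
        s = 0
        if d > 0.0:
            s = 1
        elif d < 0.0:
            s = -1
        if s == 0:
            continue
        if prev_sign > 0 and s < 0:
            maxima[nmax] = (prev_idx + 1 + t) // 2
            nmax += 1
        elif prev_sign < 0 and s > 0:
            minima[nmin] = (prev_idx + 1 + t) // 2
            nmin += 1
        prev_sign = s
        prev_idx = t
    return minima[:nmin], maxima[:nmax]


@njit(cache=True)
def _spline_envelope(X, idx, out):
    """Natural cubic spline through X[:, idx] with two mirrored edge
    extrema, evaluated at every integer sample; written into ``out``."""
    n, T = X.shape
    m = idx.shape[0]
    K = m + 4
    xk = np.empty(K)
    src = np.empty(K, np.int64)
    xk[0] = -float(idx[1])
    xk[1] = -float(idx[0])
    src[0] = idx[1]
    src[1] = idx[0]
    for j in range(m):
        xk[2 + j] = float(idx[j])
        src[2 + j] = idx[j]
    xk[K - 2] = 2.0 * (T - 1) - idx[m - 1]
    xk[K - 1] = 2.0 * (T - 1) - idx[m - 2]
    src[K - 2] = idx[m - 1]
    src[K - 1] = idx[m - 2]
    h = np.empty(K - 1)
    for j in range(K - 1):
        h[j] = xk[j + 1] - xk[j]
    nin = K - 2
    # Thomas factorisation of the tridiagonal spline system (shared
    # across channels): sub = h[i-1], diag = 2(h[i-1]+h[i]), sup = h[i]
    cp = np.empty(nin)
    denom = np.empty(nin)
    prev = 0.0
    for j in range(nin):
        dj = 2.0 * (h[j] + h[j + 1])
        if j > 0:
            dj -= h[j] * prev
        denom[j] = dj
        prev = h[j + 1] / dj
        cp[j] = prev
    dy = np.empty(K - 1)
    M = np.empty(K)
    dp = np.empty(nin)
    for ch in range(n):
        for j in range(K - 1):
            dy[j] = (X[ch, src[j + 1]] - X[ch, src[j]]) / h[j]
        for j in range(nin):
            r = 6.0 * (dy[j + 1] - dy[j])
            if j > 0:
                r -= h[j] * dp[j - 1]
            dp[j] = r / denom[j]
        M[0] = 0.0
        M[K - 1] = 0.0
        M[nin] = dp[nin - 1]
        for j in range(nin - 2, -1, -1):
            M[j + 1] = dp[j] - cp[j] * M[j + 2]
        # evaluate; eval points 0..T-1 are ascending, walk the intervals
        seg = 0
        for t in range(T):
            tt = float(t)
            while seg < K - 2 and xk[seg + 1] <= tt:
                seg += 1
            dx = tt - xk[seg]
            hi = h[seg]
            Mi = M[seg]
            Mi1 = M[seg + 1]
            b = dy[seg] - hi * (2.0 * Mi + Mi1) / 6.0
            out[ch, t] = (X[ch, src[seg]]
                          + dx * (b + dx * (0.5 * Mi
                                            + dx * (Mi1 - Mi) / (6.0 * hi))))


@njit(cache=True)
def env_mean_kernel(X, dirs):
    """Accumulated direction-wise envelopes.

    Returns ``(acc, amp, used)`` where ``acc`` sums ``e_u + e_l`` over
    usable directions, ``amp`` sums the channel-norm half-ranges, and
    ``used`` counts non-monotone projections.  Callers divide by
    ``2 * used``.
    """
    n, T = X.shape
    Kdir = dirs.shape[0]
    acc = np.zeros((n, T))
    amp = np.zeros(T)
    e_l = np.empty((n, T))
    e_u = np.empty((n, T))
    p = np.empty(T)
    used = 0
    for k in range(Kdir):
        for t in range(T):
            s = 0.0
            for i in range(n):
                s += dirs[k, i] * X[i, t]
            p[t] = s
        minima, maxima = _proj_extrema(p)
        if minima.shape[0] < 2 or maxima.shape[0] < 2:
            continue
        _spline_envelope(X, minima, e_l)
        _spline_envelope(X, maxima, e_u)
        for t in range(T):
            s = 0.0
            for i in range(n):
                acc[i, t] += e_u[i, t] + e_l[i, t]
                d = e_u[i, t] - e_l[i, t]
                s += d * d
            amp[t] += np.sqrt(s)
        used += 1
    return acc, amp, used
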