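"""Univariate empirical mode decomposition (EMD).

EMD writes a signal x(t) as a sum of intrinsic mode functions (IMFs)
plus a non-oscillating residual,

    x(t) = sum_w c_w(t) + r(t),

where each IMF c_w is a zero-mean, narrowband, amplitude- and
frequency-modulated oscillation.  IMFs are extracted by *sifting*:
cubic-spline envelopes are fit through the local maxima and minima,
their mean is subtracted, and the process repeats until the candidate
satisfies the two IMF conditions: (1) the envelope mean is (numerically)
zero and (2) the number of zero crossings and extrema differ by at most
one.  Successive IMFs are obtained by sifting the running residual, so
the decomposition telescopes and reconstruction is exact by
construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Signal",
    "EnvelopePair",
    "IMFSet",
    "SiftStop",
    "MonotoneSignalError",
    "find_extrema",
    "has_envelope_extrema",
    "envelopes",
    "is_imf",
    "sift",
    "emd_decompose",
]


class MonotoneSignalError(ValueError):
    """Raised when a signal has too few extrema to form envelopes."""


@dataclass(frozen=True)
class Signal:
    """A real, uniformly sampled time series."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if x.ndim != 1 or x.size < 8:
            raise ValueError("signal must be a 1-D vector with at least 8 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite samples")
        object.__setattr__(self, "samples", x)


@dataclass(frozen=True)
class EnvelopePair:
    """Lower/upper cubic-spline envelopes and their mean."""

    lower: np.ndarray
    upper: np.ndarray
    local_mean: np.ndarray


@dataclass
class SiftStop:
    """Rilling-style three-threshold stopping rule for sifting.

    Sifting stops once the envelope-mean amplitude ratio
    ``sd(t) = |m(t)| / a(t)`` (with ``a = (e_u - e_l)/2``) is below
    ``theta1`` on all but a fraction ``tol`` of samples and below
    ``theta2`` everywhere, or after ``max_sift`` iterations.
    """

    theta1: float = 0.05
    theta2: float = 0.5
    tol: float = 0.05
    max_sift: int = 100


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) and the trend residual."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray | None = None
    fs: float = 1.0

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = np.array(self.residual, dtype=float, copy=True)
        for c in self.imfs:
            out += c
        return out


def _as_array(x) -> np.ndarray:
    if isinstance(x, Signal):
        return x.samples
    return np.asarray(x, dtype=float)


def find_extrema(x) -> tuple[np.ndarray, np.ndarray]:
    """Locate strict local minima and maxima; plateaus count once at
    their midpoint.

    Returns ``(minima_indices, maxima_indices)``, each strictly
    increasing.  Raises :class:`MonotoneSignalError` when the signal has
    no interior extrema at all (constant or monotone); envelope
    construction additionally requires two extrema per side and raises
    there when short.
    """
    x = _as_array(x)
    if x.size < 3:
        raise MonotoneSignalError("signal too short for extrema detection")
    d = np.diff(x)
    # collapse flat runs: sign of slope with zeros carried over
    s = np.sign(d)
    nz = np.flatnonzero(s != 0)
    if nz.size < 2:
        raise MonotoneSignalError("signal is constant or monotone")
    a, b = nz[:-1], nz[1:]
    sa, sb = s[a], s[b]
    mid = (a + 1 + b) // 2  # plateau x[a+1..b] contributes its midpoint
    maxima = mid[(sa > 0) & (sb < 0)]
    minima = mid[(sa < 0) & (sb > 0)]
    if minima.size == 0 and maxima.size == 0:
        raise MonotoneSignalError("no interior extrema: monotone/trend signal")
    return minima, maxima


def has_envelope_extrema(x) -> bool:
    """True when both envelopes are constructible (>= 2 extrema per
    side), i.e. sifting can continue."""
    try:
        minima, maxima = find_extrema(x)
    except MonotoneSignalError:
        return False
    return minima.size >= 2 and maxima.size >= 2


def count_extrema(x) -> int:
    """Number of interior extrema (plateaus counted once)."""
    try:
        mins, maxs = find_extrema(x)
        return mins.size + maxs.size
    except MonotoneSignalError:
        # count whatever sign changes of the slope exist
        x = _as_array(x)
        d = np.sign(np.diff(x))
        d = d[d != 0]
        return int(np.sum(d[:-1] != d[1:])) if d.size > 1 else 0


def count_zero_crossings(x) -> int:
    """Sign changes of the sample sequence; exact zeros counted once."""
    x = _as_array(x)
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def natural_cubic_eval(xk: np.ndarray, yk: np.ndarray,
                       xe: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (xk, yk) evaluated at xe.

    ``yk`` may be (m,) or (m, n_channels); evaluation is vectorised over
    channels.  Equivalent to ``CubicSpline(..., bc_type="natural")`` but
    with far less per-call overhead — this sits in the innermost sifting
    loop.
    """
    xk = np.asarray(xk, dtype=float)
    yk = np.asarray(yk, dtype=float)
    squeeze = yk.ndim == 1
    if squeeze:
        yk = yk[:, None]
    m = xk.size
    h = np.diff(xk)
    dy = np.diff(yk, axis=0) / h[:, None]
    # second derivatives M: natural BC (M_0 = M_{m-1} = 0)
    M = np.zeros_like(yk)
    if m > 2:
        rhs = 6 * (dy[1:] - dy[:-1])
        M[1:-1] = _gtsv(h[:-1].copy(), 2 * (h[:-1] + h[1:]),
                        h[1:].copy(), rhs)
    i = np.clip(np.searchsorted(xk, xe, side="right") - 1, 0, m - 2)
    dx = (xe - xk[i])[:, None]
    hi = h[i][:, None]
    Mi, Mi1 = M[i], M[i + 1]
    b = dy[i] - hi * (2 * Mi + Mi1) / 6
    return _horner(yk[i], b, Mi, Mi1, dx, hi, squeeze)


def _horner(y0, b, Mi, Mi1, dx, hi, squeeze):
    out = y0 + dx * (b + dx * (0.5 * Mi + dx * ((Mi1 - Mi) / (6 * hi))))
    return out[:, 0] if squeeze else out


def _gtsv(dl, d, du, rhs):
    """Tridiagonal solve via LAPACK dgtsv (low per-call overhead)."""
    from scipy.linalg.lapack import dgtsv

    # dgtsv takes the sub/super-diagonals of the interior system; the
    # first sub and last super entries are dropped
    _, _, _, x, info = dgtsv(dl[1:], d, du[:-1], rhs)
    if info != 0:
        raise np.linalg.LinAlgError("tridiagonal solve failed")
    return x


def _mirror_extrema(idx: np.ndarray, val: np.ndarray, T: int):
    """Mirror the two edge-nearest extrema about each signal end.

    Keeps splines from diverging outside the span of interior extrema.
    """
    left_i = 2 * 0 - idx[:2][::-1]  # reflect about sample 0
    left_v = val[:2][::-1]
    right_i = 2 * (T - 1) - idx[-2:][::-1]
    right_v = val[-2:][::-1]
    xi = np.concatenate([left_i, idx, right_i]).astype(float)
    vi = np.concatenate([left_v, val, right_v])
    # interior extrema guarantee strictly increasing knots, but a plateau
    # midpoint at an edge can still collide — drop duplicates if any
    if xi.size > 1 and np.any(np.diff(xi) <= 0):
        xi, keep = np.unique(xi, return_index=True)
        vi = vi[keep]
    return xi, vi


def envelopes(x, extrema=None) -> EnvelopePair:
    """Cubic-spline envelopes through minima/maxima with mirrored edges.

    The local mean is ``m(t) = (e_u(t) + e_l(t)) / 2``.
    """
    xv = _as_array(x)
    T = xv.size
    if extrema is None:
        extrema = find_extrema(xv)
    minima, maxima = extrema
    if len(minima) < 2:
        raise MonotoneSignalError("insufficient minima for a lower envelope")
    if len(maxima) < 2:
        raise MonotoneSignalError("insufficient maxima for an upper envelope")
    t = np.arange(T, dtype=float)
    lo_i, lo_v = _mirror_extrema(np.asarray(minima), xv[minima], T)
    hi_i, hi_v = _mirror_extrema(np.asarray(maxima), xv[maxima], T)
    lower = natural_cubic_eval(lo_i, lo_v, t)
    upper = natural_cubic_eval(hi_i, hi_v, t)
    return EnvelopePair(lower=lower, upper=upper, local_mean=0.5 * (upper + lower))


def is_imf(c, tol: float = 0.05) -> bool:
    """Check the two IMF conditions.

    True iff ``|#zero-crossings - #extrema| <= 1`` and the envelope-mean
    magnitude stays below ``tol`` times the envelope amplitude (RMS
    ratio), i.e. the envelope mean is numerically zero.
    """
    c = _as_array(c)
    try:
        env = envelopes(c)
    except MonotoneSignalError:
        return False
    n_ext = count_extrema(c)
    n_zc = count_zero_crossings(c)
    if abs(n_zc - n_ext) > 1:
        return False
    amp = 0.5 * (env.upper - env.lower)
    scale = np.sqrt(np.mean(amp**2))
    if scale <= 0:
        return False
    return np.sqrt(np.mean(env.local_mean**2)) < tol * scale


def sift(x, stop: SiftStop | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF from ``x`` by iterative envelope-mean removal.

    Returns ``(imf, residual_input)`` with ``imf + residual_input == x``
    exactly.  If the stopping rule never fires within ``max_sift``
    iterations the current candidate is returned with a logged warning.
    """
    if stop is None:
        stop = SiftStop()
    xv = _as_array(x)
    d = xv.copy()
    converged = False
    for _ in range(stop.max_sift):
        try:
            env = envelopes(d)
        except MonotoneSignalError:
            break
        m = env.local_mean
        amp = 0.5 * (env.upper - env.lower)
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.abs(m) / np.where(amp > 0, amp, np.inf)
        if (np.mean(sd > stop.theta1) < stop.tol) and np.all(sd < stop.theta2):
            d = d - m
            converged = True
            break
        d = d - m
    if not converged:
        logger.warning("sifting did not converge within %d iterations", stop.max_sift)
    return d, xv - d


def emd_decompose(x, max_imfs: int = 12, stop: SiftStop | None = None) -> IMFSet:
    """Full EMD: repeatedly sift the residual until it is monotone or
    ``max_imfs`` is reached.  IMFs are ordered fast to slow."""
    if isinstance(x, Signal):
        fs = x.fs
        xv = x.samples.copy()
    else:
        fs = 1.0
        xv = np.asarray(x, dtype=float).copy()
    out = IMFSet(fs=fs)
    resid = xv
    for _ in range(max_imfs):
        if not has_envelope_extrema(resid):
            break
        imf, resid = sift(resid, stop)
        if not np.any(imf):
            break
        out.imfs.append(imf)
    out.residual = resid
    return out
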