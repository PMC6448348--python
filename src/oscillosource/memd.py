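"""Multivariate and noise-assisted EMD, plus band-wise IMF selection.

Multivariate EMD (MEMD) generalises sifting to an n-channel signal by
projecting it onto K quasi-uniform direction vectors on the unit
(n-1)-sphere.  For each direction the extrema of the scalar projection
are located in time, all n channels are spline-interpolated at those
times to form direction-wise lower/upper envelopes, and the local mean
is their average

    m(t) = 1/(2K) * sum_k [ e_{u,k}(t) + e_{l,k}(t) ].

Because multivariate extrema are not well defined, only the
envelope-mean stopping criterion is imposed during multivariate
sifting; the extrema/zero-crossing count condition is dropped.

The noise-assisted variant (NA-MEMD) appends independent white-Gaussian
channels before decomposing.  On white noise EMD behaves as a
quasi-dyadic filterbank, so the noise channels anchor a common
frequency-band structure and mode alignment across channels; the noise
channels' IMFs are then discarded.  Leakage from the noise channels is
suppressed by repeating the procedure over independent noise
realizations and taking a sample-wise median of the band-selected IMFs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram
from scipy.stats import norm

from .emd import (MonotoneSignalError, SiftStop, _mirror_extrema,
                  find_extrema, has_envelope_extrema, natural_cubic_eval)

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionSet",
    "MultivariateIMFSet",
    "BandDefinition",
    "BandIMF",
    "DEFAULT_BANDS",
    "direction_vectors",
    "multivariate_mean",
    "memd_decompose",
    "na_memd",
    "band_power",
    "select_band_imfs",
    "median_band_imf",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi}]")


#: The four analysis bands: theta, alpha, low beta, high beta.
DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 14.0),
    BandDefinition("beta1", 14.0, 22.0),
    BandDefinition("beta2", 22.0, 30.0),
)


@dataclass(frozen=True)
class DirectionSet:
    """K unit vectors in n dimensions used for MEMD projections."""

    vectors: np.ndarray  # K x n

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("direction vectors must have unit norm")
        if v.shape[0] < v.shape[1]:
            warnings.warn(
                "fewer directions than channels (K < n); envelope estimates "
                "may be poor",
                stacklevel=2,
            )
        object.__setattr__(self, "vectors", v)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def n(self) -> int:
        return self.vectors.shape[1]


@dataclass
class MultivariateIMFSet:
    """Channel-aligned IMFs: array (W, n, T) plus an (n, T) residual."""

    imfs: np.ndarray
    residual: np.ndarray
    fs: float = 1.0
    channel_roles: list[str] = field(default_factory=list)  # "data" | "noise"

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.residual.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _hammersley(K: int, dim: int) -> np.ndarray:
    """Hammersley point set in the unit hypercube (K points, dim dims)."""

    def radical_inverse(i, base):
        f, r = 1.0, 0.0
        while i > 0:
            f /= base
            r += f * (i % base)
            i //= base
        return r

    primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53]
    pts = np.empty((K, dim))
    pts[:, 0] = (np.arange(K) + 0.5) / K
    for d in range(1, dim):
        base = primes[(d - 1) % len(primes)]
        pts[:, d] = [radical_inverse(i + 1, base) for i in range(K)]
    return pts


def direction_vectors(n: int, K: int, seed: int = 0) -> DirectionSet:
    """Low-discrepancy direction vectors on the unit (n-1)-sphere.

    Hammersley points in the hypercube are pushed through the inverse
    Gaussian CDF and normalised, which maps low-discrepancy points to a
    quasi-uniform spread on the sphere.  ``seed`` selects a fixed random
    rotation so different seeds give different (but deterministic) sets.
    """
    if n < 2:
        raise ValueError("MEMD requires n >= 2 channels; use the emd module")
    if K < 1:
        raise ValueError("K must be positive")
    if n == 2:
        # exact equiangular set on the circle
        ang = 2 * np.pi * (np.arange(K) + 0.5) / K
        vecs = np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        pts = _hammersley(K, n)
        # clip away 0/1 before the Gaussian quantile transform
        pts = np.clip(pts, 1e-9, 1 - 1e-9)
        g = norm.ppf(pts)
        vecs = g / np.linalg.norm(g, axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    return DirectionSet(vectors=vecs @ q.T)


def _project_envelopes(X: np.ndarray, direction: np.ndarray):
    """Lower/upper multivariate envelopes for one projection direction.

    Extrema are found on the scalar projection; every channel is then
    interpolated (natural cubic spline, mirrored edge extrema) at the
    extrema times.  Returns ``(e_l, e_u)`` each (n, T), or ``None`` when
    the projection is monotone.
    """
    n, T = X.shape
    p = direction @ X
    try:
        minima, maxima = find_extrema(p)
    except MonotoneSignalError:
        return None
    if minima.size < 2 or maxima.size < 2:
        return None
    t = np.arange(T, dtype=float)
    lo_i, _ = _mirror_extrema(minima, p[minima], T)
    hi_i, _ = _mirror_extrema(maxima, p[maxima], T)
    # channel values at (possibly mirrored) extremum times: mirror indices
    # reflect back into range
    lo_src = np.clip(np.abs(lo_i), 0, 2 * (T - 1)).astype(int)
    lo_src = np.where(lo_src > T - 1, 2 * (T - 1) - lo_src, lo_src)
    hi_src = np.clip(np.abs(hi_i), 0, 2 * (T - 1)).astype(int)
    hi_src = np.where(hi_src > T - 1, 2 * (T - 1) - hi_src, hi_src)
    e_l = natural_cubic_eval(lo_i, X[:, lo_src].T, t).T
    e_u = natural_cubic_eval(hi_i, X[:, hi_src].T, t).T
    return e_l, e_u


try:  # compiled kernel for the inner sifting loop
    from ._fast import env_mean_kernel as _env_mean_kernel
except ImportError:  # pragma: no cover - numba always present in practice
    _env_mean_kernel = None


def multivariate_mean(X: np.ndarray, dirs: DirectionSet):
    """Local mean of an (n, T) signal averaged over K projections.

    Returns ``(mean, amplitude)`` where ``amplitude`` is the mean
    direction-wise envelope half-range used by the stopping rule.
    Monotone projections are skipped; if every projection is monotone a
    :class:`MonotoneSignalError` is raised.  Dispatches to a compiled
    kernel when available; :func:`multivariate_mean_reference` is the
    plain-numpy equivalent.
    """
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("multivariate mean needs an (n>=2, T) array; "
                         "use the univariate emd module for single channels")
    if _env_mean_kernel is not None:
        acc, amp, used = _env_mean_kernel(
            X, np.ascontiguousarray(dirs.vectors))
        if used == 0:
            raise MonotoneSignalError("all projections monotone: trend signal")
        return acc / (2 * used), amp / (2 * used)
    return multivariate_mean_reference(X, dirs)


def multivariate_mean_reference(X: np.ndarray, dirs: DirectionSet):
    """Pure-numpy reference implementation of :func:`multivariate_mean`."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("multivariate mean needs an (n>=2, T) array; "
                         "use the univariate emd module for single channels")
    acc = np.zeros_like(X)
    amp = np.zeros(X.shape[1])
    used = 0
    for k in range(dirs.K):
        res = _project_envelopes(X, dirs.vectors[k])
        if res is None:
            logger.debug("projection %d monotone; skipped", k)
            continue
        e_l, e_u = res
        acc += e_u + e_l
        amp += np.linalg.norm(e_u - e_l, axis=0)
        used += 1
    if used == 0:
        raise MonotoneSignalError("all projections monotone: trend signal")
    return acc / (2 * used), amp / (2 * used)


def _multivariate_sift(X: np.ndarray, dirs: DirectionSet, stop: SiftStop):
    """One multivariate IMF via envelope-mean sifting only."""
    d = X.copy()
    for _ in range(stop.max_sift):
        try:
            m, amp = multivariate_mean(d, dirs)
        except MonotoneSignalError:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = np.linalg.norm(m, axis=0) / np.where(amp > 0, amp, np.inf)
        if (np.mean(sd > stop.theta1) < stop.tol) and np.all(sd < stop.theta2):
            d = d - m
            break
        d = d - m
    return d, X - d


def _is_trend(X: np.ndarray, dirs: DirectionSet) -> bool:
    for k in range(dirs.K):
        if has_envelope_extrema(dirs.vectors[k] @ X):
            return False
    return True


def memd_decompose(
    X: np.ndarray,
    K: int = 16,
    stop: SiftStop | None = None,
    max_imfs: int = 16,
    fs: float = 1.0,
    seed: int = 0,
) -> MultivariateIMFSet:
    """Multivariate EMD of an (n, T) signal.

    Per-channel reconstruction (sum of IMFs plus residual) is exact by
    construction; mode indices are aligned across channels because every
    channel is sifted against the same projection extrema.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("memd_decompose needs n >= 2 channels")
    if stop is None:
        stop = SiftStop()
    dirs = direction_vectors(X.shape[0], K, seed=seed)
    imfs = []
    resid = X.copy()
    for _ in range(max_imfs):
        if _is_trend(resid, dirs):
            break
        imf, resid = _multivariate_sift(resid, dirs, stop)
        if not np.any(imf):
            break
        imfs.append(imf)
    W = len(imfs)
    stack = np.stack(imfs) if W else np.zeros((0,) + X.shape)
    return MultivariateIMFSet(
        imfs=stack,
        residual=resid,
        fs=fs,
        channel_roles=["data"] * X.shape[0],
    )


def na_memd(
    X_data: np.ndarray,
    n_noise: int = 12,
    noise_scale: float = 0.1,
    K: int = 16,
    seed: int = 0,
    stop: SiftStop | None = None,
    max_imfs: int = 16,
    fs: float = 1.0,
) -> MultivariateIMFSet:
    """Noise-assisted MEMD; returns IMFs of the data channels only.

    ``n_noise`` white-Gaussian channels at ``noise_scale`` times the
    pooled data standard deviation are appended before decomposition and
    their IMFs are discarded afterwards.  Accepts a single channel (the
    noise channels make the composite multivariate).
    """
    X_data = np.atleast_2d(np.asarray(X_data, dtype=float))
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    n_d, T = X_data.shape
    rng = np.random.default_rng(seed)
    noise = noise_scale * np.std(X_data) * rng.standard_normal((n_noise, T))
    composite = np.vstack([X_data, noise])
    dec = memd_decompose(composite, K=K, stop=stop, max_imfs=max_imfs,
                         fs=fs, seed=seed)
    return MultivariateIMFSet(
        imfs=dec.imfs[:, :n_d, :],
        residual=dec.residual[:n_d],
        fs=fs,
        channel_roles=["data"] * n_d,
    )


def band_power(c: np.ndarray, band: BandDefinition, fs: float) -> float:
    """Periodogram power of ``c`` integrated over ``[band.lo, band.hi]``."""
    if band.hi >= fs / 2:
        raise ValueError(
            f"band upper edge {band.hi} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    f, p = periodogram(np.asarray(c, dtype=float), fs=fs, window="boxcar")
    mask = (f >= band.lo) & (f <= band.hi)
    return float(np.trapezoid(p[mask], f[mask])) if mask.sum() > 1 else float(
        p[mask].sum()
    )


def select_band_imfs(imfs: np.ndarray, bands, fs: float) -> dict[str, int]:
    """Highest-band-power IMF index per band; ties go to the lower
    (faster) index.  ``imfs`` is (W, T)."""
    imfs = np.atleast_2d(np.asarray(imfs, dtype=float))
    if imfs.shape[0] < 1:
        raise ValueError("need at least one IMF")
    out = {}
    for band in bands:
        powers = np.array([band_power(c, band, fs) for c in imfs])
        out[band.name] = int(np.argmax(powers))  # argmax takes first on ties
    return out


@dataclass
class BandIMF:
    """Per-band median IMF over noise realizations, for one channel."""

    band: BandDefinition
    series: np.ndarray  # (T,) sample-wise median
    selections: list[int]  # chosen IMF index per realization


def median_band_imf(
    X_data: np.ndarray,
    bands=DEFAULT_BANDS,
    n_realizations: int = 30,
    n_noise: int = 12,
    noise_scale: float = 0.1,
    K: int = 16,
    seed: int = 0,
    fs: float = 1.0,
    stop: SiftStop | None = None,
    max_imfs: int = 16,
) -> list[dict[str, BandIMF]]:
    """NA-MEMD repeated over independent noise realizations.

    For every realization the highest-band-power IMF is selected per
    band (and per data channel); the returned series is the sample-wise
    median of those selections across realizations.  Returns one
    ``{band name: BandIMF}`` dict per data channel.  Realization seeds
    are spawned from ``seed`` by counter so results are reproducible and
    permutation-invariant in realization order.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    X_data = np.atleast_2d(np.asarray(X_data, dtype=float))
    n_d, T = X_data.shape
    picks: list[dict[str, list]] = [
        {b.name: [] for b in bands} for _ in range(n_d)
    ]
    sels: list[dict[str, list[int]]] = [
        {b.name: [] for b in bands} for _ in range(n_d)
    ]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(n_realizations)]
    for r_seed in child_seeds:
        dec = na_memd(X_data, n_noise=n_noise, noise_scale=noise_scale,
                      K=K, seed=r_seed, stop=stop, max_imfs=max_imfs, fs=fs)
        if dec.n_imfs == 0:
            continue
        for ch in range(n_d):
            sel = select_band_imfs(dec.imfs[:, ch, :], bands, fs)
            for name, w in sel.items():
                picks[ch][name].append(dec.imfs[w, ch, :])
                sels[ch][name].append(w)
    out = []
    for ch in range(n_d):
        per_band = {}
        for b in bands:
            chosen = picks[ch][b.name]
            if not chosen:
                series = np.zeros(T)
            else:
                series = np.median(np.stack(chosen), axis=0)
            per_band[b.name] = BandIMF(band=b, series=series,
                                       selections=sels[ch][b.name])
        out.append(per_band)
    return out
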