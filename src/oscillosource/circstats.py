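"""Circular statistics: circular-linear correlation, circular phase
distance, and the phase/frequency/correlation evaluation metrics.

The circular-linear correlation between an angular sample phi and a
linear response z is

    rho = sqrt[ (r_zc^2 + r_zs^2 - 2 r_zc r_zs r_cs) / (1 - r_cs^2) ]

with r_zc = corr(z, cos phi), r_zs = corr(z, sin phi) and
r_cs = corr(cos phi, sin phi).  It equals the multiple correlation
coefficient of regressing z on [cos phi, sin phi] and lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import InstantaneousAttributes

__all__ = [
    "DegenerateDataError",
    "EvaluationMetrics",
    "circ_lin_corr",
    "circ_lin_corr_matrix",
    "circ_distance",
    "evaluate_estimate",
]


class DegenerateDataError(ValueError):
    """Constant response or degenerate phases: correlation undefined.

    Raised (rather than returning 0) so callers can distinguish
    'no relationship' from 'no information'.
    """


@dataclass(frozen=True)
class EvaluationMetrics:
    """Agreement between an estimated and a true oscillation."""

    phase_deviation: float  # mean |circular distance|, radians, in [0, pi]
    frequency_deviation: float  # mean |f_est - f_true|, Hz
    temporal_correlation: float  # Pearson r of the series, in [-1, 1]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateDataError("constant vector in correlation")
    return float(a @ b / (na * nb))


def circ_lin_corr(phi: np.ndarray, z: np.ndarray) -> float:
    """Circular-linear correlation of phases ``phi`` (radians) with a
    linear response ``z``; returns a value in [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    z = np.asarray(z, dtype=float)
    if phi.size != z.size or phi.size < 3:
        raise ValueError("phi and z must be equal-length vectors, n >= 3")
    c, s = np.cos(phi), np.sin(phi)
    r_zc = _corr(z, c)
    r_zs = _corr(z, s)
    r_cs = _corr(c, s)
    denom = 1.0 - r_cs**2
    if denom <= 1e-15:
        raise DegenerateDataError("cos(phi) and sin(phi) are collinear")
    rho2 = (r_zc**2 + r_zs**2 - 2 * r_zc * r_zs * r_cs) / denom
    return float(np.sqrt(np.clip(rho2, 0.0, 1.0)))


def circ_lin_corr_matrix(phases: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Vectorised circular-linear correlation.

    phases : (Nt, T) phase matrix (trials x time)
    Z : (P, Nt) response rows (e.g. permutations of z)

    Returns (P, T) correlations; degenerate columns yield NaN.
    """
    phases = np.asarray(phases, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    C = np.cos(phases)
    S = np.sin(phases)
    Cc = C - C.mean(axis=0, keepdims=True)
    Sc = S - S.mean(axis=0, keepdims=True)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    nC = np.linalg.norm(Cc, axis=0)
    nS = np.linalg.norm(Sc, axis=0)
    nZ = np.linalg.norm(Zc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_zc = (Zc @ Cc) / np.outer(nZ, nC)
        r_zs = (Zc @ Sc) / np.outer(nZ, nS)
        r_cs = np.sum(Cc * Sc, axis=0) / (nC * nS)
        denom = 1.0 - r_cs**2
        rho2 = (r_zc**2 + r_zs**2 - 2 * r_zc * r_zs * r_cs[None, :]) / denom
        rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
    rho[:, denom <= 1e-15] = np.nan
    return rho


def circ_distance(phi, psi) -> np.ndarray | float:
    """Signed circular difference wrapped to (-pi, pi]."""
    d = np.angle(np.exp(1j * (np.asarray(phi, float) -
                              np.asarray(psi, float))))
    # np.angle returns [-pi, pi]; fold -pi to +pi for the (-pi, pi] convention
    d = np.where(np.isclose(d, -np.pi), np.pi, d)
    return d if np.ndim(d) else float(d)


def evaluate_estimate(
    est_attrs: InstantaneousAttributes,
    true_attrs: InstantaneousAttributes,
    est_series: np.ndarray,
    true_series: np.ndarray,
    edge_margin: float = 0.05,
) -> EvaluationMetrics:
    """Phase deviation, frequency deviation and temporal correlation
    between an estimated and a true component, excluding ``edge_margin``
    (fraction) samples at each end where Hilbert/EMD edge effects bias
    the attributes."""
    est_series = np.asarray(est_series, float)
    true_series = np.asarray(true_series, float)
    T = est_series.size
    if true_series.size != T:
        raise ValueError("series length mismatch")
    k = int(np.floor(T * edge_margin))
    sl = slice(k, T - k if k else T)
    if sl.start >= (T - k if k else T):
        raise ValueError("edge margin leaves no interior samples")
    phase_dev = float(np.mean(np.abs(
        circ_distance(est_attrs.phase[sl], true_attrs.phase[sl])
    )))
    freq_dev = float(np.mean(np.abs(
        est_attrs.frequency[sl] - true_attrs.frequency[sl]
    )))
    corr = _corr(est_series[sl], true_series[sl])
    return EvaluationMetrics(
        phase_deviation=phase_dev,
        frequency_deviation=freq_dev,
        temporal_correlation=corr,
    )
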