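"""Synthetic EEG: spherical leadfields and planted oscillatory sources.

The generator emulates a TMS-EEG style simulation study: a source of
interest (SOI) on a cortical sphere emits a sum of three
frequency-jittered oscillations (alpha, low beta, high beta) whose
amplitudes follow a 1/frequency law; one or more distractor sources add
narrowband or broadband activity; everything is projected to scalp
sensors through a three-concentric-spheres (brain / skull / scalp)
analytic dipole leadfield, and i.i.d. Gaussian sensor noise is scaled
to a target SNR defined as

    SNR = 20 * log10( std(L s_SOI + L s_distr) / std(eps) )

with the standard deviations pooled over all sensors and samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy import signal as sps

from .spectral import hilbert_attributes

__all__ = [
    "Geometry",
    "Leadfield",
    "SimulationConfig",
    "GroundTruth",
    "SensorEpoch",
    "make_spherical_leadfield",
    "make_soi",
    "make_distractors",
    "assemble_trials",
    "place_distractors_at_distances",
    "roi_around_vertex",
]

# Default head model (meters, S/m): brain, skull, scalp shells.
SHELL_RADII = (0.087, 0.092, 0.100)
SHELL_SIGMAS = (0.33, 0.0042, 0.33)
CORTEX_RADIUS = 0.070


@dataclass(frozen=True)
class Geometry:
    """Sensor and source-space geometry (positions in meters)."""

    sensor_positions: np.ndarray  # (N, 3)
    vertex_positions: np.ndarray  # (D, 3)
    vertex_orientations: np.ndarray  # (D, 3), unit norm
    roi_vertices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        sp = np.asarray(self.sensor_positions, float)
        vp = np.asarray(self.vertex_positions, float)
        vo = np.asarray(self.vertex_orientations, float)
        if sp.shape[0] < 4:
            raise ValueError("need at least 4 sensors")
        if vp.shape[0] < sp.shape[0]:
            raise ValueError("need at least as many vertices as sensors")
        if not np.allclose(np.linalg.norm(vo, axis=1), 1.0, atol=1e-9):
            raise ValueError("vertex orientations must be unit vectors")
        roi = np.asarray(self.roi_vertices, int)
        if roi.size and (roi.min() < 0 or roi.max() >= vp.shape[0]):
            raise ValueError("roi_vertices out of range")
        object.__setattr__(self, "sensor_positions", sp)
        object.__setattr__(self, "vertex_positions", vp)
        object.__setattr__(self, "vertex_orientations", vo)
        object.__setattr__(self, "roi_vertices", roi)

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.vertex_positions.shape[0]


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix L (N sensors x D vertices) and its geometry."""

    L: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        L = np.asarray(self.L, float)
        if not np.all(np.isfinite(L)):
            raise ValueError("leadfield contains non-finite entries")
        if L.shape != (self.geometry.n_sensors, self.geometry.n_vertices):
            raise ValueError("leadfield shape does not match geometry")
        object.__setattr__(self, "L", L)


@dataclass
class SimulationConfig:
    """Conditions of one simulated session."""

    soi_vertex: int = 0
    soi_center_freqs: tuple[float, ...] = (10.1, 18.0, 27.5)
    freq_jitter: float = 0.5
    distractor_spec: list = field(default_factory=list)  # (vertex, center|"broadband")
    snr_db: float = 0.0
    n_trials: int = 100
    fs: float = 1000.0
    duration: float = 1.0
    seed: int = 0
    soi_amplitude_scale: float = 1.0  # a_j = scale / f_center_j

    def __post_init__(self):
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        T = self.duration * self.fs
        if abs(T - round(T)) > 1e-9:
            raise ValueError("duration * fs must be an integer sample count")
        centers = np.sort(np.asarray(self.soi_center_freqs, float))
        if np.any(np.diff(centers) < 2 * self.freq_jitter):
            warnings.warn(
                "SOI center frequencies closer than twice the jitter: "
                "jitter bands overlap", stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruth:
    """Per-trial planted truth for evaluation."""

    components: np.ndarray  # (3, T) clean SOI oscillations
    phases: np.ndarray  # (3, T) analytic phase of each component
    frequencies: np.ndarray  # (3, T) instantaneous frequency, Hz
    distractors: np.ndarray  # (k, T)
    clean_projection: np.ndarray  # (N, T) noiseless sensor signal


@dataclass
class SensorEpoch:
    """One trial of multichannel sensor data."""

    data: np.ndarray  # (N, T)
    fs: float
    sensor_positions: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Spherical leadfield
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int, hemisphere: bool = False) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    if hemisphere:
        z = i / n  # z in (0, 1): upper hemisphere
    else:
        z = 1 - 2 * i / n
    phi = np.pi * (1 + np.sqrt(5)) * i
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shell_potential_coeffs(
    b: float,
    n_max: int = 100,
    radii=SHELL_RADII,
    sigmas=SHELL_SIGMAS,
) -> np.ndarray:
    """Legendre coefficients of the scalp potential of a unit radial
    dipole at radius ``b`` inside concentric conductive shells.

    For each harmonic degree n the radial solution in shell j is
    ``A_j r^n + B_j r^{-(n+1)}``; the innermost shell additionally
    carries the primary dipole term ``Q_n r^{-(n+1)}`` with
    ``Q_n = n b^{n-1} / (4 pi sigma_1)``.  Continuity of potential and
    radial current at each interface plus zero current at the outer
    surface give a small linear system per degree, solved numerically.
    The scalp potential is ``V(R, gamma) = sum_n c_n P_n(cos gamma)``.
    """
    radii = np.asarray(radii, float)
    sigmas = np.asarray(sigmas, float)
    S = len(radii)
    R = radii[-1]
    if not (0 < b < radii[0]):
        raise ValueError("dipole radius must lie inside the innermost shell")
    # scale radii by R to keep powers well conditioned
    rs = radii / R
    bs = b / R
    coeffs = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        Q = n * bs ** (n - 1) / (4 * np.pi * sigmas[0])
        # unknowns: A_1, (A_j, B_j) for j = 2..S  -> 2S - 1 unknowns
        m = 2 * S - 1
        M = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_A(j):  # shell j (1-based) -> column of A_j
            return 0 if j == 1 else 2 * j - 3

        def col_B(j):
            return 2 * j - 2  # j >= 2

        row = 0
        for j in range(1, S):  # interface between shell j and j+1 at rs[j-1]
            r = rs[j - 1]
            # potential continuity
            M[row, col_A(j)] += r**n
            if j >= 2:
                M[row, col_B(j)] += r ** -(n + 1)
            M[row, col_A(j + 1)] -= r**n
            M[row, col_B(j + 1)] -= r ** -(n + 1)
            if j == 1:
                rhs[row] = -Q * r ** -(n + 1)
            row += 1
            # radial current continuity
            M[row, col_A(j)] += sigmas[j - 1] * n * r ** (n - 1)
            if j >= 2:
                M[row, col_B(j)] -= sigmas[j - 1] * (n + 1) * r ** -(n + 2)
            M[row, col_A(j + 1)] -= sigmas[j] * n * r ** (n - 1)
            M[row, col_B(j + 1)] += sigmas[j] * (n + 1) * r ** -(n + 2)
            if j == 1:
                rhs[row] = sigmas[0] * (n + 1) * Q * r ** -(n + 2)
            row += 1
        # outer boundary: zero radial current at rs[-1] = 1
        M[row, col_A(S)] = sigmas[-1] * n
        M[row, col_B(S)] = -sigmas[-1] * (n + 1)
        sol = np.linalg.solve(M, rhs)
        c_n = sol[col_A(S)] + sol[col_B(S)]  # r = 1 in scaled units
        # undo the radius scaling: V has units 1/R^2 relative to scaled form
        coeffs[n] = c_n / R**2
        if n > 10 and abs(coeffs[n]) < 1e-12 * np.abs(coeffs[1:n]).max():
            break
    return coeffs


def make_spherical_leadfield(
    n_sensors: int,
    n_vertices: int,
    seed: int = 0,
    radii=SHELL_RADII,
    sigmas=SHELL_SIGMAS,
    cortex_radius: float = CORTEX_RADIUS,
    n_max: int = 100,
) -> Leadfield:
    """Analytic three-concentric-spheres EEG leadfield.

    Sensors sit quasi-equidistant on the upper hemisphere of the scalp
    sphere; vertices are quasi-uniform on an inner cortical sphere with
    radial dipole orientations.  ``seed`` applies a deterministic random
    rotation to the vertex lattice (and an azimuthal rotation to the
    sensors) so repeated calls with the same seed are bit-identical.
    """
    if n_sensors < 4 or n_vertices < n_sensors:
        raise ValueError("need n_sensors >= 4 and n_vertices >= n_sensors")
    rng = np.random.default_rng(seed)
    sensors = _fibonacci_sphere(n_sensors, hemisphere=True)
    theta = rng.uniform(0, 2 * np.pi)
    rot_z = np.array([
        [np.cos(theta), -np.sin(theta), 0],
        [np.sin(theta), np.cos(theta), 0],
        [0, 0, 1],
    ])
    sensors = sensors @ rot_z.T * radii[-1]
    verts_unit = _fibonacci_sphere(n_vertices)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.linalg.det(q))
    verts_unit = verts_unit @ q.T
    vertices = verts_unit * cortex_radius
    geometry = Geometry(
        sensor_positions=sensors,
        vertex_positions=vertices,
        vertex_orientations=verts_unit,
    )
    coeffs = shell_potential_coeffs(cortex_radius, n_max=n_max,
                                    radii=radii, sigmas=sigmas)
    # cos(angle) between each sensor and each vertex direction
    su = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
    cosg = np.clip(su @ verts_unit.T, -1.0, 1.0)
    L = npleg.legval(cosg, coeffs)
    return Leadfield(L=L, geometry=geometry)


def roi_around_vertex(geometry: Geometry, vertex: int,
                      radius_m: float = 0.02) -> np.ndarray:
    """Vertices within a chord distance of the given vertex (an ROI
    analogue of an anatomical label around the planted source)."""
    d = np.linalg.norm(
        geometry.vertex_positions - geometry.vertex_positions[vertex], axis=1
    )
    return np.flatnonzero(d <= radius_m)


def place_distractors_at_distances(
    geometry: Geometry,
    soi_vertex: int,
    distances_m=(0.03, 0.05, 0.07, 0.09, 0.11),
    jitter_m: float = 1e-3,
    seed: int = 0,
) -> list[int]:
    """Vertices closest to the requested chord distances from the SOI,
    after jittering each distance by up to ``jitter_m``.

    Distances beyond the source-space extent fall back to the farthest
    feasible vertex with a warning.
    """
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(
        geometry.vertex_positions - geometry.vertex_positions[soi_vertex],
        axis=1,
    )
    out = []
    for target in distances_m:
        t = target + rng.uniform(-jitter_m, jitter_m)
        if t > d.max():
            warnings.warn(
                f"requested distractor distance {target * 100:.1f} cm exceeds "
                "source-space extent; using farthest vertex", stacklevel=2,
            )
            t = d.max()
        out.append(int(np.argmin(np.abs(d - t))))
    return out


# ---------------------------------------------------------------------------
# Oscillatory sources
# ---------------------------------------------------------------------------

def _jitter_trajectory(rng: np.random.Generator, T: int, fs: float,
                       jitter: float) -> np.ndarray:
    """Smooth instantaneous-frequency offset clipped to +/- jitter Hz.

    White Gaussian noise is low-pass filtered (2nd-order Butterworth at
    1 Hz) to a slowly drifting trajectory, scaled to a standard
    deviation of half the jitter, and hard-clipped at the band edges.
    """
    if jitter == 0:
        return np.zeros(T)
    w = rng.standard_normal(T + int(fs))  # extra second to settle the filter
    sos = sps.butter(2, min(1.0, fs / 4 - 1e-6), btype="lowpass", fs=fs,
                     output="sos")
    sm = sps.sosfiltfilt(sos, w)[int(fs) // 2:int(fs) // 2 + T]
    sm = sm - sm.mean()
    sd = sm.std()
    if sd > 0:
        sm = sm * (jitter / 2) / sd
    return np.clip(sm, -jitter, jitter)


def make_soi(config: SimulationConfig, trial_seed: int) -> GroundTruth:
    """The SOI's three frequency-jittered oscillations for one trial.

    Component j oscillates at ``center_j`` plus a smooth trajectory
    within ``+/- freq_jitter`` Hz; its amplitude is proportional to
    ``1 / center_j`` (1/f amplitude law on the center frequency).  The
    stored ground-truth phase is the analytic (Hilbert) phase of each
    clean component.  Distractor and projection fields are filled by
    :func:`assemble_trials`.
    """
    T = config.n_samples
    fs = config.fs
    rng = np.random.default_rng(trial_seed)
    n_comp = len(config.soi_center_freqs)
    comps = np.empty((n_comp, T))
    freqs = np.empty((n_comp, T))
    for j, fc in enumerate(config.soi_center_freqs):
        traj = _jitter_trajectory(rng, T, fs, config.freq_jitter)
        f_inst = fc + traj
        phase = 2 * np.pi * np.cumsum(f_inst) / fs + rng.uniform(0, 2 * np.pi)
        amp = config.soi_amplitude_scale / fc
        c = amp * np.cos(phase)
        comps[j] = c - c.mean()
        freqs[j] = f_inst
    phases = np.stack([
        hilbert_attributes(c, fs).phase for c in comps
    ])
    return GroundTruth(
        components=comps,
        phases=phases,
        frequencies=freqs,
        distractors=np.zeros((0, T)),
        clean_projection=np.zeros((0, T)),
    )


def make_distractors(config: SimulationConfig, trial_seed: int) -> np.ndarray:
    """Distractor time series for one trial, one row per spec entry.

    A numeric spec entry emits a single frequency-jittered oscillation
    at that center frequency with the same 1/f amplitude law as the SOI;
    ``"broadband"`` emits white noise FIR-filtered to [4, 30] Hz with an
    RMS comparable to a mid-band narrowband distractor.
    """
    if not config.distractor_spec:
        raise ValueError("distractor_spec is empty")
    T = config.n_samples
    fs = config.fs
    rng = np.random.default_rng(trial_seed)
    rows = []
    for _, kind in config.distractor_spec:
        if isinstance(kind, str):
            if kind != "broadband":
                raise ValueError(f"unknown distractor kind {kind!r}")
            numtaps = min(T // 3 * 2 - 1, 301)
            numtaps += 1 - numtaps % 2
            taps = sps.firwin(numtaps, [4.0, 30.0], pass_zero=False, fs=fs,
                              window="hamming")
            w = rng.standard_normal(T + 2 * numtaps)
            x = sps.filtfilt(taps, [1.0], w)[numtaps:numtaps + T]
            target_rms = config.soi_amplitude_scale / 17.0 / np.sqrt(2)
            x = x / x.std() * target_rms
        else:
            fc = float(kind)
            traj = _jitter_trajectory(rng, T, fs, config.freq_jitter)
            phase = (2 * np.pi * np.cumsum(fc + traj) / fs
                     + rng.uniform(0, 2 * np.pi))
            x = config.soi_amplitude_scale / fc * np.cos(phase)
        rows.append(x - x.mean())
    return np.stack(rows)


def assemble_trials(
    L: Leadfield, config: SimulationConfig
) -> tuple[list[SensorEpoch], list[GroundTruth]]:
    """Simulate ``n_trials`` noisy sensor epochs with retained truth.

    Per trial: ``y = L s_SOI + L s_distr + eps`` with the noise scaled
    so the pooled-std SNR definition holds exactly for that trial's
    realized clean projection.  The master seed spawns independent
    per-trial substreams, so increasing ``n_trials`` never reshuffles
    earlier trials.
    """
    D = L.geometry.n_vertices
    if config.soi_vertex >= D or any(
        v >= D for v, _ in config.distractor_spec
    ):
        raise ValueError("config references vertices outside the leadfield")
    ss = np.random.SeedSequence(config.seed)
    epochs, truths = [], []
    for child in ss.spawn(config.n_trials):
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        gt = make_soi(config, trial_seed)
        soi_sum = gt.components.sum(axis=0)
        clean = np.outer(L.L[:, config.soi_vertex], soi_sum)
        if config.distractor_spec:
            distr = make_distractors(config, trial_seed + 1)
            for (v, _), row in zip(config.distractor_spec, distr):
                clean += np.outer(L.L[:, v], row)
            gt.distractors = distr
        gt.clean_projection = clean
        std_clean = clean.std()
        if std_clean == 0:
            raise ValueError("zero clean-signal power: SNR undefined")
        target_noise_std = std_clean / 10 ** (config.snr_db / 20)
        rng = np.random.default_rng(trial_seed + 2)
        eps = rng.standard_normal(clean.shape)
        eps *= target_noise_std / eps.std()
        epochs.append(SensorEpoch(
            data=clean + eps,
            fs=config.fs,
            sensor_positions=L.geometry.sensor_positions,
        ))
        truths.append(gt)
    return epochs, truths


def realized_snr_db(epoch: SensorEpoch, truth: GroundTruth) -> float:
    """Recompute the SNR definition on a generated trial."""
    noise = epoch.data - truth.clean_projection
    return 20 * np.log10(truth.clean_projection.std() / noise.std())
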