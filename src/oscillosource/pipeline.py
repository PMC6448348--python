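"""Orchestration: method variants, the simulation evaluation, and the
experimental-style phase-to-response analysis.

Eight method variants are compared.  Sensor-level variants decompose
raw sensor series near the target; source-level variants first unmix
the data spatially (REST re-referencing, smoothness-prior inverse, ROI
power ranking) and decompose the recovered source series; ``bandpass``
replaces the decomposition with zero-phase FIR filters on the top-power
ROI source; ``emd_sl`` reverses the order — NA-EMD per electrode, then
source localization of each band's electrode-wise IMFs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import memd as memd_mod
from .circstats import EvaluationMetrics, evaluate_estimate
from .clusterstats import ClusterResult, cluster_permutation_1d, \
    cluster_permutation_2d, delaunay_adjacency
from .inverse import InverseConfig, extract_roi_sources, nearest_sensors, \
    rest_transform, solve_inverse
from .memd import DEFAULT_BANDS, BandDefinition, median_band_imf
from .spectral import InstantaneousAttributes, fir_bandpass, \
    hilbert_attributes, preprocess_epoch
from .synthdata import GroundTruth, Leadfield, SensorEpoch, \
    SimulationConfig, assemble_trials, make_spherical_leadfield, \
    roi_around_vertex

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS",
    "PipelineConfig",
    "TrialDecomposition",
    "Table1Report",
    "run_variant",
    "evaluate_simulation",
    "run_experimental_analysis",
    "make_simulation_setup",
]

VARIANTS = (
    "1_sensor", "4_sensors", "1plus_sensors",
    "1_source", "4_sources", "1plus_sources",
    "bandpass", "emd_sl",
)


@dataclass
class PipelineConfig:
    """Shared knobs for decomposition and statistics."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    n_noise_channels: int = 12
    n_realizations: int = 30
    K: int = 16
    noise_scale: float = 0.1
    max_imfs: int = 16
    inverse: InverseConfig = field(default_factory=InverseConfig)
    edge_margin: float = 0.05
    seed: int = 0


@dataclass
class TrialDecomposition:
    """Band-wise decomposition of one trial.

    ``series[band]`` is (n_emitted_channels, T); ``attributes[band]``
    holds one :class:`InstantaneousAttributes` per emitted channel
    (None where the band series is degenerate).
    """

    series: dict[str, np.ndarray]
    attributes: dict[str, list[InstantaneousAttributes | None]]
    fs: float


def _attrs_or_none(x: np.ndarray, fs: float):
    if np.std(x) == 0:
        return None
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return hilbert_attributes(x, fs)


def _decompose_channels(X: np.ndarray, fs: float, cfg: PipelineConfig,
                        seed: int, emit: slice | list) -> TrialDecomposition:
    """NA-MEMD median band IMFs of (n, T) data, emitting a channel
    subset."""
    per_channel = median_band_imf(
        X, bands=cfg.bands, n_realizations=cfg.n_realizations,
        n_noise=cfg.n_noise_channels, noise_scale=cfg.noise_scale,
        K=cfg.K, seed=seed, fs=fs, max_imfs=cfg.max_imfs,
    )
    emit_idx = (list(range(*emit.indices(len(per_channel))))
                if isinstance(emit, slice) else list(emit))
    series, attributes = {}, {}
    for b in cfg.bands:
        rows = np.stack([per_channel[ch][b.name].series for ch in emit_idx])
        series[b.name] = rows
        attributes[b.name] = [_attrs_or_none(r, fs) for r in rows]
    return TrialDecomposition(series=series, attributes=attributes, fs=fs)


def _bandpass_decomposition(x: np.ndarray, fs: float,
                            cfg: PipelineConfig) -> TrialDecomposition:
    """FIR comparator: zero-phase bandpass of one series per band, with
    symmetric zero-padding so the lowest band's filter fits."""
    T = x.size
    lo_min = min(b.lo for b in cfg.bands)
    numtaps = int(np.ceil(3 * fs / lo_min))
    numtaps += 1 - numtaps % 2
    need = 3 * numtaps
    if T < need:
        pre = (need - T) // 2
        post = need - T - pre
        xp = np.pad(x, (pre, post))
    else:
        pre, xp = 0, x
    series, attributes = {}, {}
    for b in cfg.bands:
        y = fir_bandpass(xp, b, fs)[pre:pre + T]
        series[b.name] = y[None, :]
        attributes[b.name] = [_attrs_or_none(y, fs)]
    return TrialDecomposition(series=series, attributes=attributes, fs=fs)


def _source_series(epoch: SensorEpoch, leadfield: Leadfield,
                   cfg: PipelineConfig, n_sources: int) -> np.ndarray:
    roi = leadfield.geometry.roi_vertices
    if roi.size == 0:
        raise ValueError("leadfield geometry has an empty ROI")
    y_rest = rest_transform(epoch, leadfield)
    est = solve_inverse(y_rest, leadfield, cfg.inverse)
    series, _ = extract_roi_sources(est, roi, n_sources)
    return series


def run_variant(
    trials: list[SensorEpoch],
    leadfield: Leadfield,
    variant: str,
    cfg: PipelineConfig | None = None,
    target_position=None,
) -> list[TrialDecomposition]:
    """Band-wise decomposition of every trial under one method variant.

    ``target_position`` (3-vector, meters) selects the nearest sensors
    for the sensor-level variants; it defaults to the position of the
    first ROI vertex.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {VARIANTS}")
    if cfg is None:
        cfg = PipelineConfig()
    geom = leadfield.geometry
    if target_position is None:
        if geom.roi_vertices.size == 0:
            raise ValueError("no target position and no ROI to derive one")
        target_position = geom.vertex_positions[geom.roi_vertices[0]]
    t_start = time.perf_counter()
    ss = np.random.SeedSequence(cfg.seed)
    trial_seeds = [int(c.generate_state(1)[0] % (2**31))
                   for c in ss.spawn(len(trials))]
    out = []
    for epoch, seed in zip(trials, trial_seeds):
        fs = epoch.fs
        if variant == "1_sensor":
            idx = nearest_sensors(geom, target_position, 1)
            dec = _decompose_channels(epoch.data[idx], fs, cfg, seed, [0])
        elif variant == "4_sensors":
            idx = nearest_sensors(geom, target_position, 4)
            dec = _decompose_channels(epoch.data[idx], fs, cfg, seed,
                                      slice(None))
        elif variant == "1plus_sensors":
            idx = nearest_sensors(geom, target_position, 4)
            dec = _decompose_channels(epoch.data[idx], fs, cfg, seed, [0])
        elif variant == "1_source":
            s = _source_series(epoch, leadfield, cfg, 1)
            dec = _decompose_channels(s, fs, cfg, seed, [0])
        elif variant == "4_sources":
            s = _source_series(epoch, leadfield, cfg, 4)
            dec = _decompose_channels(s, fs, cfg, seed, slice(None))
        elif variant == "1plus_sources":
            s = _source_series(epoch, leadfield, cfg, 4)
            dec = _decompose_channels(s, fs, cfg, seed, [0])
        elif variant == "bandpass":
            s = _source_series(epoch, leadfield, cfg, 1)
            dec = _bandpass_decomposition(s[0], fs, cfg)
        elif variant == "emd_sl":
            dec = _emd_then_localize(epoch, leadfield, cfg, seed)
        out.append(dec)
    logger.info("variant %s: %d trials in %.1f s", variant, len(trials),
                time.perf_counter() - t_start)
    return out


def _emd_then_localize(epoch: SensorEpoch, leadfield: Leadfield,
                       cfg: PipelineConfig, seed: int) -> TrialDecomposition:
    """EMD + SL: per-electrode NA-EMD, then per-band source localization
    of the electrode-wise band IMFs.

    Band matching across electrodes uses each electrode's own
    band-power argmax (no cross-electrode mode pairing).
    """
    fs = epoch.fs
    N = epoch.data.shape[0]
    ss = np.random.SeedSequence(seed)
    ch_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(N)]
    band_mats = {b.name: np.empty_like(epoch.data) for b in cfg.bands}
    for ch in range(N):
        per_band = median_band_imf(
            epoch.data[ch:ch + 1], bands=cfg.bands,
            n_realizations=cfg.n_realizations, n_noise=cfg.n_noise_channels,
            noise_scale=cfg.noise_scale, K=cfg.K, seed=ch_seeds[ch], fs=fs,
            max_imfs=cfg.max_imfs,
        )[0]
        for b in cfg.bands:
            band_mats[b.name][ch] = per_band[b.name].series
    roi = leadfield.geometry.roi_vertices
    series, attributes = {}, {}
    for b in cfg.bands:
        y_rest = rest_transform(band_mats[b.name], leadfield)
        est = solve_inverse(y_rest, leadfield, cfg.inverse)
        s, _ = extract_roi_sources(est, roi, 1)
        series[b.name] = s
        attributes[b.name] = [_attrs_or_none(s[0], fs)]
    return TrialDecomposition(series=series, attributes=attributes, fs=fs)


# ---------------------------------------------------------------------------
# Simulation evaluation
# ---------------------------------------------------------------------------

def make_simulation_setup(
    n_sensors: int = 32,
    n_vertices_gen: int = 600,
    n_vertices_rec: int = 300,
    seed: int = 0,
    roi_radius_m: float = 0.02,
    soi_direction=(0.0, 0.0, 1.0),
) -> tuple[Leadfield, Leadfield, int]:
    """Generation and reconstruction leadfields over the same sensors.

    Source generation and inversion use different cortical meshes
    (different vertex counts) to avoid committing the inverse crime.
    The SOI is the generation vertex closest to ``soi_direction``; the
    reconstruction geometry's ROI collects vertices within
    ``roi_radius_m`` of that position.  Returns
    ``(L_generation, L_reconstruction, soi_vertex)``.
    """
    L_gen = make_spherical_leadfield(n_sensors, n_vertices_gen, seed=seed)
    L_rec = make_spherical_leadfield(n_sensors, n_vertices_rec, seed=seed)
    d = np.asarray(soi_direction, float)
    d = d / np.linalg.norm(d)
    soi_vertex = int(np.argmax(L_gen.geometry.vertex_positions @ d))
    soi_pos = L_gen.geometry.vertex_positions[soi_vertex]
    rec_dists = np.linalg.norm(
        L_rec.geometry.vertex_positions - soi_pos, axis=1)
    roi = np.flatnonzero(rec_dists <= roi_radius_m)
    if roi.size == 0:
        roi = np.array([int(np.argmin(rec_dists))])
    geom = replace(L_rec.geometry, roi_vertices=roi)
    L_rec = Leadfield(L=L_rec.L, geometry=geom)
    return L_gen, L_rec, soi_vertex


def _component_band(center: float, bands) -> str | None:
    for b in bands:
        if b.lo <= center < b.hi:
            return b.name
    return None


@dataclass
class Table1Report:
    """Mean metrics per variant and scenario, plus pairwise tests."""

    table: pd.DataFrame  # rows: (scenario, variant); metric columns
    pairwise: pd.DataFrame  # scenario, variant_a, variant_b, metric, p
    per_repetition: pd.DataFrame  # raw per-trial averaged metrics


def _evaluate_trial(
    dec: TrialDecomposition | None,
    truth: GroundTruth,
    config: SimulationConfig,
    cfg: PipelineConfig,
    truth_injection: bool = False,
) -> dict[str, float]:
    """Metrics for one trial, averaged over SOI components (and over
    emitted channels when a variant yields several)."""
    fs = config.fs
    per_comp: list[EvaluationMetrics] = []
    for j, fc in enumerate(config.soi_center_freqs):
        bname = _component_band(fc, cfg.bands)
        if bname is None:
            continue
        true_attrs = InstantaneousAttributes(
            amplitude=np.abs(truth.components[j]),
            phase=truth.phases[j],
            frequency=truth.frequencies[j],
            fs=fs,
        )
        if truth_injection:
            per_comp.append(evaluate_estimate(
                true_attrs, true_attrs, truth.components[j],
                truth.components[j], cfg.edge_margin))
            continue
        chans = []
        for ch, attrs in enumerate(dec.attributes[bname]):
            if attrs is None:
                continue
            chans.append(evaluate_estimate(
                attrs, true_attrs, dec.series[bname][ch],
                truth.components[j], cfg.edge_margin))
        if chans:
            per_comp.append(EvaluationMetrics(
                phase_deviation=float(np.mean([m.phase_deviation
                                               for m in chans])),
                frequency_deviation=float(np.mean([m.frequency_deviation
                                                   for m in chans])),
                temporal_correlation=float(np.mean([m.temporal_correlation
                                                    for m in chans])),
            ))
    return {
        "phase_deviation": float(np.mean([m.phase_deviation
                                          for m in per_comp])),
        "frequency_deviation": float(np.mean([m.frequency_deviation
                                              for m in per_comp])),
        "temporal_correlation": float(np.mean([m.temporal_correlation
                                               for m in per_comp])),
    }


def evaluate_simulation(
    scenarios: dict[str, tuple[Leadfield, Leadfield, SimulationConfig]],
    variants=VARIANTS,
    cfg: PipelineConfig | None = None,
    truth_injection: bool = False,
) -> Table1Report:
    """Run variants over simulated scenarios and tabulate mean phase
    deviation, frequency deviation and temporal correlation.

    Each scenario supplies ``(L_generation, L_reconstruction, config)``;
    ``config.n_trials`` is the number of repetitions.  Metrics are
    averaged across the SOI components and repetitions; pairwise
    two-sided t-tests compare variants per scenario and metric.
    """
    if cfg is None:
        cfg = PipelineConfig()
    rows = []
    for scen_name, (L_gen, L_rec, sim_cfg) in scenarios.items():
        epochs, truths = assemble_trials(L_gen, sim_cfg)
        target = L_gen.geometry.vertex_positions[sim_cfg.soi_vertex]
        for variant in variants:
            if truth_injection:
                decs = [None] * len(epochs)
            else:
                decs = run_variant(epochs, L_rec, variant, cfg,
                                   target_position=target)
            for rep, (dec, truth) in enumerate(zip(decs, truths)):
                m = _evaluate_trial(dec, truth, sim_cfg, cfg,
                                    truth_injection)
                rows.append({"scenario": scen_name, "variant": variant,
                             "repetition": rep, **m})
    per_rep = pd.DataFrame(rows)
    metrics = ["phase_deviation", "frequency_deviation",
               "temporal_correlation"]
    table = per_rep.groupby(["scenario", "variant"])[metrics].mean()
    tests = []
    for scen_name in per_rep["scenario"].unique():
        sub = per_rep[per_rep["scenario"] == scen_name]
        for va, vb in combinations(sorted(sub["variant"].unique()), 2):
            a = sub[sub["variant"] == va]
            b = sub[sub["variant"] == vb]
            for metric in metrics:
                p = stats.ttest_ind(a[metric], b[metric]).pvalue
                tests.append({"scenario": scen_name, "variant_a": va,
                              "variant_b": vb, "metric": metric,
                              "p": float(p)})
    return Table1Report(table=table, pairwise=pd.DataFrame(tests),
                        per_repetition=per_rep)


# ---------------------------------------------------------------------------
# Experimental-style analysis
# ---------------------------------------------------------------------------

def filter_trials_by_mep(
    mep: np.ndarray,
    cap_mv: float | None = None,
    drop_median_k: int = 0,
) -> np.ndarray:
    """Trial-selection mask: drop trials above ``cap_mv`` and then the
    ``drop_median_k`` trials closest to the median MEP, focusing the
    analysis on trials with clearly low or high excitability."""
    mep = np.asarray(mep, float)
    keep = np.ones(mep.size, dtype=bool)
    if cap_mv is not None:
        keep &= mep <= cap_mv
    if drop_median_k > 0:
        idx = np.flatnonzero(keep)
        med = np.median(mep[idx])
        order = idx[np.argsort(np.abs(mep[idx] - med), kind="stable")]
        keep[order[:drop_median_k]] = False
    return keep


def run_experimental_analysis(
    epochs: list[SensorEpoch],
    mep: np.ndarray,
    leadfield: Leadfield,
    variant: str = "1_source",
    cfg: PipelineConfig | None = None,
    mep_cap_mv: float | None = None,
    drop_median_k: int = 0,
    n_perm: int = 1000,
    alpha: float = 0.05,
    preprocess: bool = False,
    do_2d: bool = False,
    target_position=None,
) -> dict[str, ClusterResult]:
    """Phase-to-MEP correlation with cluster permutation control.

    Per kept trial the chosen variant extracts one band-wise component;
    its Hilbert phase enters an (Nt, T) phase matrix per band which is
    tested against the MEP vector.  When ``do_2d`` is set an additional
    sensor x time test (keys ``"<band>_2d"``) decomposes every sensor.
    """
    if cfg is None:
        cfg = PipelineConfig()
    mep = np.asarray(mep, float)
    if mep.size != len(epochs):
        raise ValueError("MEP length must match the number of trials")
    keep = filter_trials_by_mep(mep, mep_cap_mv, drop_median_k)
    epochs = [e for e, k in zip(epochs, keep) if k]
    mep = mep[keep]
    if preprocess:
        processed = []
        for e in epochs:
            data, fs = preprocess_epoch(e.data, e.fs)
            processed.append(SensorEpoch(data=data, fs=fs,
                                         sensor_positions=e.sensor_positions))
        epochs = processed
    decs = run_variant(epochs, leadfield, variant, cfg,
                       target_position=target_position)
    results: dict[str, ClusterResult] = {}
    for b in cfg.bands:
        phases = []
        for dec in decs:
            attrs = dec.attributes[b.name][0]
            T = dec.series[b.name].shape[-1]
            phases.append(attrs.phase if attrs is not None else np.zeros(T))
        phases = np.stack(phases)
        results[b.name] = cluster_permutation_1d(
            phases, mep, n_perm=n_perm, alpha=alpha, seed=cfg.seed)
    if do_2d:
        N = epochs[0].data.shape[0]
        fs = epochs[0].fs
        ss = np.random.SeedSequence(cfg.seed + 1)
        seeds = [int(c.generate_state(1)[0] % (2**31))
                 for c in ss.spawn(len(epochs))]
        sensor_phases = {b.name: [] for b in cfg.bands}
        for epoch, seed in zip(epochs, seeds):
            per_ch = median_band_imf(
                epoch.data, bands=cfg.bands,
                n_realizations=cfg.n_realizations,
                n_noise=cfg.n_noise_channels, noise_scale=cfg.noise_scale,
                K=cfg.K, seed=seed, fs=fs, max_imfs=cfg.max_imfs)
            for b in cfg.bands:
                ph = np.stack([
                    _phase_or_zero(per_ch[ch][b.name].series, fs)
                    for ch in range(N)
                ])
                sensor_phases[b.name].append(ph)
        pos = epochs[0].sensor_positions
        adjacency = delaunay_adjacency(pos) if pos is not None else None
        for b in cfg.bands:
            arr = np.stack(sensor_phases[b.name], axis=1)  # (N, Nt, T)
            results[f"{b.name}_2d"] = cluster_permutation_2d(
                arr, mep, adjacency=adjacency, n_perm=n_perm, alpha=alpha,
                seed=cfg.seed)
    return results


def _phase_or_zero(x: np.ndarray, fs: float) -> np.ndarray:
    a = _attrs_or_none(x, fs)
    return a.phase if a is not None else np.zeros(x.size)
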