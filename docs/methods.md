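# Methods

`oscillosource` implements a source-level analysis chain for oscillatory
EEG: spatial unmixing by a smoothness-prior Bayesian inverse, temporal
unmixing by noise-assisted multivariate empirical mode decomposition
(NA-MEMD), Hilbert instantaneous attributes, and circular-linear
statistics linking prestimulus phase to a per-trial behavioural
response under cluster-permutation control.  This note records the
models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Empirical mode decomposition

EMD writes a signal as `x(t) = Σ_w c_w(t) + r(t)` where each intrinsic
mode function (IMF) `c_w` satisfies two conditions: the mean of its
cubic-spline upper and lower envelopes is (numerically) zero, and its
zero-crossing and extrema counts differ by at most one.  Sifting
repeatedly subtracts the envelope mean `m(t) = (e_u + e_l)/2` until the
conditions hold; further IMFs come from sifting the running residual.
Reconstruction is exact by construction (telescoping), which the tests
assert to 1e-10 relative.

Numerical choices:

- **Stopping rule.** The envelope-mean conditions carry no numeric
  tolerance of their own, so sifting stops with a Rilling-style
  three-threshold criterion: `sd(t) = |m(t)|/a(t)` with
  `a = (e_u − e_l)/2` must fall below 0.05 on at least 95% of samples
  and below 0.5 everywhere, with a hard cap of 100 iterations.
- **Boundary handling.** The two edge-nearest extrema are mirrored
  about each signal end before spline fitting; without this, natural
  splines diverge outside the span of interior extrema and corrupt the
  envelopes.  Envelope-sensitive metrics additionally flag 5% of
  samples at each edge as unreliable and exclude them.
- **Plateaus** contribute a single extremum at their midpoint;
  zero crossings are sign changes of the sample sequence with exact
  zeros counted once.

## Multivariate and noise-assisted EMD

MEMD projects an n-channel signal onto K quasi-uniform directions of
the unit (n−1)-sphere (Hammersley points pushed through the inverse
Gaussian CDF and normalised; K = 16 by default).  Per direction, the
projection's extrema define interpolation times at which all channels
are splined, giving direction-wise envelopes; the local mean is
`m(t) = (1/2K) Σ_k (e_{u,k} + e_{l,k})`.  Because multivariate extrema
are ill-defined, only the envelope-mean criterion stops multivariate
sifting (the count condition is dropped).  The same Rilling thresholds
as in the univariate case are used, applied to `‖m(t)‖` relative to the
mean direction-wise envelope half-range.

NA-MEMD appends 12 independent white-Gaussian channels at 10% of the
pooled data standard deviation (`noise_scale = 0.1`; the literature
prescribes "small" noise without a number, and 10% keeps the assist
channels from competing with the data while still anchoring the
quasi-dyadic band structure).  Their IMFs are discarded.  Because small
noise leakages remain, the decomposition is repeated over independent
noise realizations (30 by default); per realization the IMF with the
highest periodogram power in each band (θ 4–8, α 8–14, β₁ 14–22,
β₂ 22–30 Hz) is selected, and the sample-wise median across
realizations is the band component.  Selection happens per realization
*before* the median, and ties go to the faster IMF.  Band power uses a
raw rectangular-window periodogram: the trials are one second long, so
Welch averaging would cost all frequency resolution for no variance
benefit.

A caveat worth knowing: with one data channel plus 12 noise channels
the composite lives in 13 dimensions, and K = 16 directions sample that
sphere sparsely.  On unlucky noise draws a direction lands nearly
orthogonal to the data channel, its envelope absorbs part of the data
oscillation, and 10–35% of a pure tone's energy can leak into the
neighbouring mode.  The median over realizations is precisely the
mitigation; at K = 64 the single-shot leakage disappears.

The inner sifting loop (projection, extrema, natural splines, averaging)
is compiled with numba; a pure-numpy reference implementation of the
same arithmetic is kept and the test suite asserts their outputs agree
to 1e-12.

## Synthetic data

The generator emulates a TMS-EEG simulation study.  The source of
interest (SOI) is a sum of three oscillations whose instantaneous
frequencies wander within ±0.5 Hz of 10.1, 18 and 27.5 Hz; the
frequency trajectory is low-pass-filtered white noise (2nd-order
Butterworth at 1 Hz) scaled to a standard deviation of half the jitter
and clipped at the band edges, and the phase is the cumulative integral
of instantaneous frequency with a uniform random offset.  Amplitudes
follow a 1/f law applied to the *center* frequency (`a_j ∝ 1/f_j`),
matching the usual reading of a 1/frequency amplitude power law; the
stored ground-truth phase of each component is its analytic (Hilbert)
phase.  Distractors are either a single frequency-jittered oscillation
with the same amplitude law, or white noise FIR-filtered to 4–30 Hz
with RMS matched to a mid-band (17 Hz) narrowband distractor.

Sensor data are `y = L s_SOI + L s_distr + ε` with i.i.d. Gaussian ε
scaled per trial so that `SNR = 20·log10(std(clean)/std(ε))` holds
exactly, with the standard deviations pooled over all sensors and
samples (one noise scale per trial).  The master seed spawns
independent per-trial substreams, so growing the trial count never
reshuffles earlier trials.

The leadfield is an analytic three-concentric-spheres model (brain /
skull / scalp radii 8.7 / 9.2 / 10 cm, conductivities 0.33 / 0.0042 /
0.33 S/m): for each harmonic degree the shell coefficients solve the
continuity conditions at the interfaces plus zero current at the scalp,
assembled as a small linear system per degree rather than a transcribed
closed form; the homogeneous limit is checked against the one-boundary
closed form in the tests.  Sensors sit quasi-equidistant (golden-spiral
lattice) on the upper scalp hemisphere; vertices are quasi-uniform on a
7 cm cortical sphere with radial (fixed) dipole orientations.
Distractor placement resolves requested chord distances to the nearest
vertices with ≤1 mm jitter — on a sphere, chord and geodesic orderings
agree, and the target distances are approximate anyway.

What the generator does *not* emulate: realistic cortical folding and
the resulting orientation structure, skull-thickness variation,
correlated (biological) noise, artifacts, or volume-conducted muscle
activity.  Passing tests therefore show that the chain recovers planted
oscillations through a linear, spatially smooth mixing process at
controlled SNR — not that it survives every pathology of real EEG.

## Epoch preprocessing

Recorded epochs are polyphase-downsampled to 1 kHz, cropped to the
prestimulus window −500 to −22 ms (left-closed right-open, 478 samples
— the sample convention is a package choice; the window and the 2479-
sample padding target are the experiment's), zero-padded symmetrically
to 2479 samples, bandpass-filtered 1–45 Hz with a 5th-order Butterworth
applied forward and backward (zero phase), and unpadded.  Padding
before filtering limits edge transients on the short epoch; note that
the 1 Hz high-pass edge can only attenuate, not remove, a DC offset
over a 0.478 s block (the offset is spectrally a ~1 Hz-wide boxcar),
and 50/60 Hz line components are attenuated by roughly 27 dB, both of
which the tests pin against the filter-response oracle.

## Source localization

The forward model is `y = L s + ε`.  REST re-referencing maps
average-referenced data to an approximate reference at infinity via
`L·pinv(L_avg)·Y_avg` with the reference-free leadfield; its residual
error is exactly a spatially constant offset (the irreducible reference
ambiguity), which the tests verify, and is small for superficial
sources under the montage.

The inverse solver is a two-hyperparameter evidence-optimized weighted
minimum norm: per time sample `y ~ N(0, λ_s L G Lᵀ + λ_n I)` with a
Gaussian spatial-coherence prior `G_ij = exp(−d_ij²/2w²)` (default
width w = 10 mm, the scale of coherently active cortical patches).
Writing `G = R Rᵀ` and `B = L R`, expectation-maximisation updates
(λ_s, λ_n) in the N-dimensional SVD basis of B; for this Gaussian model
the free energy equals the log evidence, the EM trace is non-decreasing
(asserted per run), and the estimate is the posterior mean.  The noise
variance can be held fixed (e.g. vanishing for noiseless data), in
which case only the source scale is optimised.  This solver is the
package's own smoothness-prior design in the LORETA family; a different
solver can be swapped in wherever a `solve_inverse`-shaped callable is
accepted.  Per trial, the region-of-interest vertices are ranked by
temporal power and the top one (univariate analysis) or four
(multivariate) source series are extracted; ranking is per-trial
because the strongest ROI source genuinely moves from trial to trial.

## Circular statistics and cluster inference

The circular-linear correlation between phases φ across trials and a
linear response z is
`ρ² = (r_zc² + r_zs² − 2 r_zc r_zs r_cs)/(1 − r_cs²)` with
`r_zc = corr(z, cos φ)`, `r_zs = corr(z, sin φ)`,
`r_cs = corr(cos φ, sin φ)`; it equals the multiple correlation of z on
[cos φ, sin φ] (asserted against an independent least-squares oracle to
1e-10) and lies in [0, 1].  The squared denominator is the standard
statistic; degenerate inputs (constant z, collinear cos/sin) raise a
distinct error rather than returning 0.  Circular distance is
`angle(exp(i(φ−ψ)))` on (−π, π].  Simulation metrics are the time-mean
absolute circular distance of phase, the time-mean absolute
instantaneous-frequency difference, and the Pearson correlation of the
series, all excluding the 5% edge margins (mean *absolute* circular
distance, so opposite-phase errors cannot cancel).

Cluster permutation: per time sample the observed ρ is converted to a
one-sided t-like score against the null distribution obtained by
permuting z across trials (the same permutations reused at every sample
and sensor — required for valid max-statistic control).  Scores above
the 1−α quantile of a t distribution with (permutations − 1) degrees of
freedom form clusters — contiguous runs in time, or connected
components of (same-sensor temporal neighbours ∨ same-sample spatial
neighbours) in the 2-D sensor×time test, with sensor adjacency from a
pruned Delaunay triangulation.  The cluster statistic is the summed
score; its p-value is the fraction of permutations whose *maximum*
cluster statistic is at least as large.  This per-sample construction
is a design parameter: the max-statistic calibration holds for any
cluster-forming rule, and the family-wise error under the null is
verified at 0.05 ± 0.03 over 200 synthetic datasets.  Frequency bands
are tested separately; no correction across bands is applied.

## Method variants

Eight variants are compared on simulated data: NA-(M)EMD of the 1 or 4
sensors nearest the target (`1_sensor`, `4_sensors`; `1plus_sensors`
decomposes 4 jointly but analyses only the nearest), NA-(M)EMD of the
top-power ROI source(s) after REST + inversion (`1_source`,
`4_sources`, `1plus_sources`), zero-phase FIR bandpass of the top
source (`bandpass`; least-squares design, 20% transition bands, taps =
three cycles of the low cutoff, applied forward-backward), and
`emd_sl`, which decomposes every electrode first and then
source-localizes each band's electrode-wise IMF matrix.  For `emd_sl`
the band IMFs are matched across electrodes by each electrode's own
band-power argmax; no cross-electrode mode pairing is attempted (none
is well defined for spontaneous activity).  Variants that emit several
channels are scored per channel and averaged.

## Problem sizes

Test and acceptance runs use deliberately scaled-down conditions, all
stated here as the package's own choices: 24-sensor montage, 400-vertex
generation and 500-vertex reconstruction spheres (distinct meshes so
inversion never sees the generating mesh), 250 Hz sampling of 1 s
trials, 8 NA-MEMD noise realizations, 20 repetitions, single 14 Hz
narrowband distractor ~5 cm from the SOI at 0 dB pooled SNR.  Montage
density is the quality-limiting size: below ~20 sensors the inverse
leaves enough mixed noise in the extracted source to cap the recovered
temporal correlation near 0.90.  Reconstruction-mesh density matters
for the multivariate source variants specifically, because they are
scored across all four power-ranked ROI sources and a coarse mesh
pushes the 2nd–4th picks off the projection peak.  A full-scale
analysis would use a 61-channel montage, thousands of vertices, 1 kHz,
and 30 realizations; quality rises accordingly (the desk-scale
single-source temporal correlation is ≈0.92 against ≈0.97 at full
scale).  One full-scale contrast shrinks a lot at desk scale: the
EMD-then-localize variant, far behind the source-level decompositions
in the full-scale study, lands within a few hundredths of them here —
per-electrode band selection over a modest montage behaves much like
the (strong) bandpass comparator.  Instantaneous-frequency deviation is the metric most
sensitive to the scaled conditions, since the centred-difference
derivative amplifies residual in-band noise that a denser montage and
more realizations would have suppressed.  Localization checks plant
sources in the upper cortical hemisphere: an EEG montage covers only
the upper head, so antipodal dipoles are unobservable by construction.

## Known limitations

- Spherical geometry only; user-supplied leadfields are accepted but
  no BEM/FEM construction is provided.
- EMD separates oscillations reliably only when their frequencies
  differ by roughly a factor ≥1.5; the 14 Hz distractor against the
  18 Hz component is intentionally inside that hard regime, and the
  β₁ band is accordingly the weakest.
- The evidence-optimized solver assumes stationary, white sensor noise
  within a trial.
- Circular-linear correlation is invariant to phase rotation, so
  cluster findings say *that* phase matters, not *which* phase is
  optimal.
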