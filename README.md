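# oscillosource

Source-level unmixing of oscillatory EEG: spatial unmixing by a
smoothness-prior Bayesian inverse, temporal unmixing by noise-assisted
multivariate empirical mode decomposition (NA-MEMD), and circular
statistics linking prestimulus oscillation phase to a per-trial
behavioural response (e.g. motor-evoked-potential amplitude in TMS-EEG
experiments) with cluster-permutation control of multiple comparisons.

The package is for researchers who want to analyse the *instantaneous*
phase and frequency of narrowband brain oscillations at the cortical
source level — where volume conduction has been partially undone —
rather than at the scalp, and to test whether that phase predicts a
behavioural readout.  A synthetic-data generator with planted
oscillatory sources makes the entire chain testable without any
recordings.

## The model

EEG sensors see a linear mixture of cortical sources,
`y(t) = L s(t) + ε(t)`, with leadfield `L ∈ ℝ^{N×D}` and `N ≪ D`.  The
inverse is solved as an evidence-optimized weighted minimum norm with
a Gaussian spatial-coherence prior (a LORETA-style smoothness
assumption): `y ~ N(0, λ_s L G Lᵀ + λ_n I)` with
`G_ij = exp(−d_ij²/2w²)`, the hyperparameters (λ_s, λ_n) fitted by
free-energy (log-evidence) ascent, after REST re-referencing
(`Y_rest = L pinv(L_avg) Y_avg`).

The strongest source(s) in a region of interest are decomposed into
intrinsic mode functions, `x(t) = Σ_w a_w(t)ψ_w(t) + r(t)`, by sifting:
cubic-spline envelope means are subtracted until each mode has a
numerically zero envelope mean and balanced zero-crossing/extrema
counts.  The multivariate form builds envelopes from K projections of
the n-channel signal (`m(t) = (1/2K) Σ_k [e_{u,k} + e_{l,k}]`); adding
12 white-noise channels (NA-MEMD) anchors a quasi-dyadic filterbank and
aligns modes across channels, and a sample-wise median over 30 noise
realizations removes noise leakage.  The IMF with the highest power in
each band (θ 4–8, α 8–14, β₁ 14–22, β₂ 22–30 Hz) is the band component;
its Hilbert transform yields instantaneous amplitude, phase and
frequency.

Phase is linked to a linear response z by the circular-linear
correlation

    ρ² = (r_z,cosφ² + r_z,sinφ² − 2 r_z,cosφ r_z,sinφ r_φ) / (1 − r_φ²)

computed per time sample across trials, and significant time (or
sensor×time) windows are found with a max-statistic cluster permutation
test (sum-of-t cluster statistic, 1000 permutations).

## A worked example

`examples/01_emd_basics.py` decomposes a 4 Hz + 18 Hz mixture:

```
3 IMFs extracted
  IMF 0: dominant  18.0 Hz,  25.6% of input energy
  IMF 1: dominant   4.0 Hz,  58.7% of input energy
  IMF 2: dominant   3.0 Hz,  20.5% of input energy
max reconstruction error: 2.22e-16  (exact by construction)
```

The two tones separate into the first two modes (fast first), the third
mode carries residual slow content from the 4 Hz tone's boundary, and
the decomposition reproduces the input to machine precision.

`examples/03_source_localization.py` plants a 10 Hz dipole under a
32-channel montage at 10 dB SNR and inverts:

```
true vertex 89, estimated 89, localization error 0.00 cm
free energy rose monotonically over 14 iterations: True
```

The remaining examples walk through band-wise median IMFs (`02`), the
full phase→response cluster analysis on simulated trials (`04`), and
the sensor- versus source-level variant comparison (`05`).

A thin CLI covers the batch steps
(`oscillosource simulate|decompose|correlate|evaluate --config cfg.yaml
--seed 0 --out ...`); the YAML schema is documented in
`oscillosource/cli.py`.

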