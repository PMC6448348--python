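"""Noise-assisted MEMD with band-wise median IMFs.

A single noisy channel carrying alpha (10 Hz) and low-beta (18 Hz)
oscillations is decomposed with 12 white-noise assist channels over
several noise realizations; per band the highest-power IMF is selected
and the sample-wise median across realizations is reported.  The
printed correlations show how well each band's median IMF isolates the
corresponding planted oscillation.
"""

import numpy as np

from oscillosource.memd import DEFAULT_BANDS, median_band_imf

fs = 500.0
t = np.arange(500) / fs
rng = np.random.default_rng(0)
alpha = np.cos(2 * np.pi * 10 * t)
beta1 = 0.6 * np.cos(2 * np.pi * 18 * t + 1.0)
x = alpha + beta1 + 0.3 * rng.standard_normal(t.size)

out = median_band_imf(x, bands=DEFAULT_BANDS, n_realizations=8,
                      seed=1, fs=fs)[0]
for name, truth in [("alpha", alpha), ("beta1", beta1)]:
    series = out[name].series
    r = np.corrcoef(series, truth)[0, 1]
    print(f"{name:6s} median IMF vs planted tone: r = {r:+.3f} "
          f"(selected IMF indices per realization: {out[name].selections})")
print("a correlation near 1 means the band IMF isolated that oscillation")
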