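"""Separate time scales with the modified 13-month KZ filter.

Builds a monthly series holding an annual cycle, an 11-year cycle and white
noise, applies KZ(13-modified, 2), and shows that the seasonal component is
annihilated while the 11-year component passes almost untouched.
"""
import numpy as np

import kzepi as kz

i = np.arange(600)
rng = np.random.default_rng(0)
series = kz.MonthlyTimeSeries(
    (1960, 1),
    10.0 * np.sin(2 * np.pi * i / 12)      # strong seasonal cycle
    + 1.0 * np.sin(2 * np.pi * i / 132)    # weak 11-year cycle
    + rng.normal(0, 2.0, size=600),        # noise
)

window = kz.modified_13_window()
filtered = kz.kz_filter(series, window, k=2)  # trims 12 months per end

idx = np.arange(len(filtered)) + (filtered.start - series.start).n
solar_band = np.sin(2 * np.pi * idx / 132)
amplitude_11y = np.linalg.lstsq(
    np.column_stack([solar_band, np.cos(2 * np.pi * idx / 132)]),
    filtered.values, rcond=None,
)[0]

print(f"input std:                {series.values.std():.2f}")
print(f"filtered std:             {filtered.values.std():.2f}")
print(f"analytic gain at 1/12:    {kz.kz_gain(window, 2, 1 / 12):.2e}")
print(f"analytic gain at 1/132:   {kz.kz_gain(window, 2, 1 / 132):.3f}")
print(f"recovered 11-yr amplitude: {np.hypot(*amplitude_11y):.3f} (true 1.0)")
# The seasonal cycle (amplitude 10) and most noise are gone; the 11-year
# cycle survives with ~97% of its amplitude: the filter isolates the long
# term (>1 year) time scale.
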