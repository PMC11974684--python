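"""Plate-reader assay summaries: melt-curve Tm and trans-cleavage rate.

Tm is the temperature of the thermal-shift fluorescence peak; a curve whose
maximum sits on the 25/99 degC grid boundary has no detectable peak and is
flagged.  Trans-cleavage reporter curves are summarised by their initial
OLS slope.
"""

import numpy as np

from cas12akin import initial_rate, tm_from_melt
from cas12akin.synthetic import generate_melt_curve, generate_trans_curve

melt = generate_melt_curve(tm=48.0, noise_sd=5.0, seed=1)
result = tm_from_melt(melt)
print(f"Tm = {result.tm:.0f} degC (no_peak={result.no_peak})")

flat = generate_melt_curve(tm=99.0, width=30.0)  # maximum on the boundary
print(f"destabilised protein: no_peak={tm_from_melt(flat).no_peak}")

trans = generate_trans_curve(rate=0.01, plateau=1000.0,
                             times=np.arange(0.0, 301.0, 1.0), noise_sd=2.0, seed=2)
rate = initial_rate(trans)  # slope over the first 10% of the span
print(f"initial trans-cleavage rate = {rate:.2f} RFU/s "
      f"(early slope of plateau*(1-exp(-k*t)) ~ plateau*k = 10)")
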