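"""qPCR standard-curve quantification and library arithmetic.

Fits the 20-0.002 fmol ten-fold dilution series (run in duplicate),
quantifies unknowns, converts a serum time course into percent-full-length
stability, and prints the closed-form library numbers: single-strand
molecular weight with and without an 11-kDa PEG, and the diversity bound
implied by a 5 nmol injection.
"""

import math

import numpy as np

import selexseed as sx

rng = np.random.default_rng(1)
slope_ideal = -1 / math.log10(2)
standards = []
for q in (20.0, 2.0, 0.2, 0.02, 0.002):
    for _ in range(2):  # duplicates
        standards.append((q, 20.0 + slope_ideal * math.log10(q) + rng.normal(0, 0.05)))

curve = sx.fit_standard_curve(standards)
print(f"standard curve: slope {curve.slope:.3f} Cq/decade, "
      f"R^2 {curve.r_squared:.4f}, efficiency {curve.efficiency:.3f}")
print(f"sample at Cq 22.5 -> {sx.quantify(curve, 22.5):.4f} fmol")

# serum stability: quantities at 0, 1, 3, 18 h
series = sx.stability_series([0.0, 1.0, 3.0, 18.0], [2.0, 1.86, 1.22, 0.31])
for t, pct in zip(series.timepoints_h, series.percent_full_length):
    print(f"  {t:>4.0f} h: {pct:5.1f}% full length")

mw = sx.ssdna_molecular_weight(80, "equimolar")
mw_peg = sx.ssdna_molecular_weight(80, "equimolar", peg_kda=11.0)
count, order = sx.diversity_from_amount(5.0)
print(f"\n80-nt ssDNA: {mw:.2f} kDa (~{round(mw)} kDa); "
      f"with 11 kDa PEG: {mw_peg:.2f} kDa (~{round(mw_peg)} kDa)")
print(f"5 nmol at one copy per sequence: {count:.3g} molecules (order {order:.0e})")
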