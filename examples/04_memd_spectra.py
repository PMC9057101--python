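"""Decompose coefficient time series into timescales and characterise them.

MEMD splits the k-dimensional NMF expression coefficients into
mode-aligned IMFs (fast to slow); Hilbert spectral analysis assigns each
IMF a peak fluctuation frequency in cycles/day.
"""

import numpy as np

import seizmod
from seizmod.bandpower import normalize_and_stack
from seizmod.hht import find_circadian_imf, marginal_spectrum, peak_frequency
from seizmod.memd import memd
from seizmod.nmf import select_k

circ = np.zeros((5, 6))
circ[:3] = 1.0
ultra = np.zeros((5, 6))
ultra[3:, :3] = 1.0
mods = [seizmod.ModulatorSpec(1.0, 1.0, 0.4, circ), seizmod.ModulatorSpec(0.25, 0.8, 2.0, ultra)]
power = seizmod.generate_band_power(6, 4.0, mods, seed=3)
dm = normalize_and_stack(power)
f = select_k(dm.values, 3, 6)

s = memd(f.H, n_dirs=64, seed=7)
spec = marginal_spectrum(s)
print(f"{s.M} IMFs from k={f.k} coefficient series, T={s.T} epochs")
print("IMF  peak freq (cycles/day)   cycle length (days)")
for i in range(s.M):
    pf = peak_frequency(spec, i)
    print(f"{i + 1:3d}  {pf:20.3f}   {1 / pf:11.3f}")
ci = find_circadian_imf(spec)
print(f"circadian IMF: {ci + 1 if ci is not None else 'absent'}")
# The planted 1-day rhythm should appear as an IMF peaking at 1 cycle/day
# and the 6 h rhythm as one peaking at 4 cycles/day.
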