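"""Generate a small synthetic subject with planted band-power modulators.

A circadian (1 day) and an ultradian (6 h) modulator drive the amplitude
envelopes of band-limited noise carriers; seizures are scheduled whose
evolution shapes depend on the modulator states at onset.
"""

import numpy as np

import seizmod

rec = seizmod.generate_subject(
    n_channels=2, fs=180.0, duration_days=1.0, n_seizures=6, seed=42
)

print(f"channels: {rec.n_channels}, fs: {rec.fs} Hz, duration: {rec.duration_s / 86400:.2f} days")
print(f"signal matrix: {rec.signals.shape} ({rec.signals.nbytes / 1e6:.0f} MB)")
for i, mod in enumerate(rec.truth["modulators"]):
    print(
        f"modulator {i}: period {mod['period_days']} days, "
        f"amplitude {mod['amplitude']} (log band-power units)"
    )
print(f"seizure onsets (s): {np.round(rec.seizure_onsets_s)}")
print(
    "planted dissimilarity range:",
    f"{rec.truth['planted_dissimilarity'].min():.2f}",
    "-",
    f"{rec.truth['planted_dissimilarity'].max():.2f}",
)
# The planted dissimilarity encodes how far apart two seizures are in
# modulator state: the regression stage should be able to explain it from
# the recovered band-power fluctuations.
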