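"""Quantitative EEG markers: band powers, spectral edge frequency, entropy.

Simulates one recovering animal per arm, runs the 1-30 Hz spectral
pipeline and prints the end-of-observation SEF and spectral entropy.
Higher SEF means more of the power sits at higher frequencies; entropy
near 1 means power is spread evenly (a complex signal), near 0 means a
single rhythm dominates.
"""

import numpy as np

from neoqeeg import bandpass, qeeg_timecourse
from neoqeeg.spectral import QEEGConfig, animal_qeeg_value
from neoqeeg.synthetic import GROUPS, CohortSpec, generate_animal_eeg

spec = CohortSpec(seed=0)
qcfg = QEEGConfig(window_s=4.0, segment_s=4.0)

print(f"{'arm':6s} {'SEF (Hz)':>9s} {'entropy':>8s} {'delta frac':>11s}")
for group in GROUPS:
    rec = generate_animal_eeg(spec, group, np.random.default_rng(1))
    tc = qeeg_timecourse(bandpass(rec), qcfg)
    sef = animal_qeeg_value(tc, "sef_hz", mode="terminal")
    ent = animal_qeeg_value(tc, "entropy", mode="terminal")
    ok = tc[~tc["suppressed"]]
    delta_frac = (ok["power_delta"] / ok["power_total"]).mean()
    print(f"{group:6s} {sef:9.2f} {ent:8.3f} {delta_frac:11.2f}")

print(
    "\nThe hydrogen arm recovers the flattest spectrum (highest SEF and "
    "entropy); the cooled arm stays the most delta-dominated. Suppressed "
    "(isoelectric) epochs are excluded from the markers."
)
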