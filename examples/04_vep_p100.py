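"""Flash-VEP averaging and P100 extraction.

Generates the standard stimulation protocol (10 trains of 10 flashes at
1 Hz, 10 s between trains = 100 trials), averages the noisy trials and
reads the P100 latency and amplitude, then compares arms.
"""

import numpy as np
import pandas as pd

from neoqeeg import analyze_vep, group_vep_compare
from neoqeeg.synthetic import GROUPS, CohortSpec, generate_vep_trials

spec = CohortSpec(seed=0)

rows = []
for gi, group in enumerate(GROUPS):
    for k in range(spec.n_per_group[group]):
        trials, times, stim = generate_vep_trials(spec.profiles[group].vep, seed=1000 * gi + k)
        res = analyze_vep(trials, times)
        rows.append({"animal": f"{group}-{k}", "group": group,
                     "latency_ms": res.p100_latency_ms, "amplitude_uv": res.p100_amplitude_uv})

df = pd.DataFrame(rows)
out = group_vep_compare(df)
print(out["summary"].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"\nlatency one-way ANOVA:   F = {out['latency_ms'].statistic:.2f}, "
      f"p = {out['latency_ms'].p_value:.2g}")
print(f"amplitude one-way ANOVA: F = {out['amplitude_uv'].statistic:.2f}, "
      f"p = {out['amplitude_uv'].p_value:.2g}")
print(out["latency_ms"].pairwise.to_string(index=False))
print(
    "\nLatency separates the cooled arm (configured 15 ms shorter than "
    "untreated); amplitude is equal across arms by construction and should "
    "stay non-significant."
)
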