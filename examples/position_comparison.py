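"""Does tag position change classification accuracy?

Simulates cohorts whose anterior-scute (scute1) tag attenuates movement
signal (gain 0.5) and adds noise (0.1 g), runs the pipeline per position
over three seeds, and fits the beta regression with a Tukey-adjusted
pairwise position contrast — the same comparison used to argue for
mid-dorsal (scute3) placement.
"""

import pandas as pd

from accethogram.classify import SplitSpec
from accethogram.pipeline import PipelineSettings, position_effect_analysis, run_pipeline
from accethogram.synthgen import default_cohort_config, simulate_cohort

rows = []
for seed in range(3):
    cfg = default_cohort_config(
        seed=seed, n_individuals=6, duration_s=180,
        scute1_gain=0.5, scute1_extra_noise_g=0.1,
    )
    settings = PipelineSettings(
        window_lengths=(2,), frequencies=(100, 2),
        split=SplitSpec(seed=seed), mtry_grid=(4,), n_trees=300,
    )
    acc, _ = run_pipeline(simulate_cohort(cfg), settings)
    rows.append(acc)
grid = pd.concat(rows, ignore_index=True)

print(grid[["position", "freq_hz", "accuracy"]].to_string(index=False))
print("\nmean accuracy by position:")
print(grid.groupby("position")["accuracy"].mean().round(4).to_string())

analysis = position_effect_analysis(grid)
print("\npairwise position contrast (logit scale, Tukey-adjusted):")
print(analysis["contrast_table"].to_string(index=False))
# A negative scute1 - scute3 estimate with small p says the degraded
# anterior placement classifies behaviour significantly worse.
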