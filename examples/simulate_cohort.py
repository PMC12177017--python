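"""Generate a synthetic labelled accelerometer cohort and write it to disk.

Builds the default captive-turtle cohort (8 individuals, two tag positions,
100 Hz / 8-bit / ±2 g loggers, five behaviours), writes logger-style and
annotation CSVs, and prints what was produced.
"""

from pathlib import Path

from accethogram.synthgen import default_cohort_config, simulate_cohort, write_fixture

cfg = default_cohort_config(seed=42, duration_s=120)
cohort = simulate_cohort(cfg)
out = Path("scratch/example_fixtures")
paths = write_fixture(cohort, out)

print(f"cohort: {cfg.n_individuals} individuals x 2 tag positions = {len(cohort)} traces")
trace, ann = cohort[0]
print(f"first trace: {trace.individual_id}/{trace.position}, "
      f"{len(trace)} samples at {trace.sample_rate_hz} Hz, "
      f"range ±{trace.dynamic_range_g} g, {trace.resolution_bits}-bit")
print(f"first bouts: {[(b, round(s, 1), round(e, 1)) for b, s, e in ann.bouts[:3]]}")
print(f"wrote {len(paths)} CSV files to {out}/")
# Each trace file holds timestamp,ax_g,ay_g,az_g rows; each annotation file
# the ground-truth behaviour bouts used later as classification labels.
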