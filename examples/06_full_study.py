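"""The full pipeline: five field conditions × three replicates, end to end.

Runs a shortened synthetic study through every stage (dipole, RMSF,
displacement, essential dynamics, contact surface area, energetics) and
prints the per-condition dipole window statistics from the written CSVs.
"""

from pathlib import Path

import pandas as pd

from kinfield.pipeline import RunConfig, run_pipeline

out = Path("scratch") / "full_study"
cfg = RunConfig(seed=1, out_dir=out)
cfg.generator = {"duration": 4000.0}      # ps; the study default is 30 ns
cfg.rmsf_window = (1000.0, 4000.0)
cfg.displacement_window = (2000.0, 4000.0)
cfg.block = 2000.0
cfg.n_points = 64

manifest = run_pipeline(cfg)
print(f"stages failed: {manifest['failed_stages'] or 'none'}")
print(f"outputs written: {len(manifest['outputs'])} files in {out}/")
print()
stats = pd.read_csv(out / "dipole_window_stats.csv")
print(stats.to_string(index=False))
print()
print("Each row pools the three replicates of one field condition over the")
print("late time window: the X/-X fields mainly stretch or compress the")
print("dipole magnitude, while Y/-Y rotate its azimuth away from the")
print("no-field mean in opposite directions.")
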