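"""Run a small config-driven experiment end to end.

Writes a YAML run configuration, executes it (world generation, simulation
grid, estimator fits, rate aggregation), and prints the resulting
false-positive-rate table.
"""

import tempfile
from pathlib import Path

import pandas as pd
import yaml

from galton import RunConfig, run

outdir = Path(tempfile.mkdtemp(prefix="galton_run_"))
config = {
    "world": {"n_nations": 60, "seed": 5},
    "output_dir": str(outdir),
    "grid": {"lambdas": [0.2, 0.8], "rhos": [0.2, 0.8], "rs": [0.0],
             "sigma_sources": ["linguistic"], "n_reps": 20},
    "methods": ["naive", "family_fe", "phylo_ranef"],
    "seed": 11,
    "log_level": "WARNING",
}
cfg_path = outdir / "config.yaml"
cfg_path.write_text(yaml.safe_dump(config))

result = run(RunConfig.from_yaml(cfg_path))
rates = pd.read_csv(result["rates"])
cols = ["lambda", "rho", "method", "rate", "ci_low", "ci_high"]
print(rates[cols].to_string(index=False))
print(f"\n{result['n_fits']} fits written to {outdir}.")
print("Rates are the share of replicates whose 95% interval excluded zero "
      "(r = 0,\nso these are false-positive rates); naive rates climb with "
      "autocorrelation\nstrength while the linguistic random-intercept model "
      "stays near 5%.")
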