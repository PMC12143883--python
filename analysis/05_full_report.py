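"""End-to-end pipeline run: one seeded configuration, one report bundle.

Drives `pairbond.pipeline.run_experiment` exactly as the CLI does:
photometry cohort + preference arms, summary CSVs and a stats report
carrying the config hash. Running it twice with the same seed yields
byte-identical outputs.
"""

from pathlib import Path

from pairbond.pipeline import RunConfig, run_experiment
from pairbond.synthetic import SimConfig, study_default_effects

ARMS = ("Gq:CNO", "Gq:saline", "Gi:CNO", "Gi:saline", "mCherry:CNO", "mCherry:saline")

config = RunConfig(
    mode="synthetic",
    seed=42,
    out_dir=Path("results") / "full_run",
    n_animals=7,
    day="day7",
    preference_arms=ARMS,
    n_per_arm=8,
    sim=SimConfig(seed=42, group_effects=study_default_effects()),
)
written = run_experiment(config)
for name, path in written.items():
    print(f"{name}: {path}")
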