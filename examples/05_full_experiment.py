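"""Simulate a complete experiment and run the whole analysis pipeline.

Generates the 4 cover x 2 fertilization x 6 block design with all raw
inputs (logger series, tracer table, plates, dilution assays), runs every
stage, and prints the mixed-model ANOVA summary.
"""

import tempfile
from pathlib import Path

import pandas as pd

from soilncycle.pipeline import run_pipeline
from soilncycle.synth import ExperimentConfig, generate_experiment

exp = generate_experiment(ExperimentConfig(), seed=11)
print(f"{len(exp.plots)} plots, {len(exp.temperature)} logger series, "
      f"{len(exp.plates)} plate wells")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    exp.write(tmp / "in")
    manifest = run_pipeline(tmp / "in", tmp / "out", config=exp.config, seed=11)
    anova = pd.read_csv(tmp / "out" / "anova_table.csv")
    recovery = pd.read_csv(tmp / "out" / "recovery_summary.csv")

print("\nmixed-model ANOVA (F values, significance, R2):")
cols = ["response", "f_cover", "sig_cover", "f_fert", "sig_fert",
        "r2_marginal", "r2_conditional"]
print(anova[cols].round(3).to_string(index=False))

print("\nmean recovery of fertilizer 15N (% of applied):")
print(recovery.round(1).to_string(index=False))
print("\nan R2c well above R2m flags responses with strong block structure")
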