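"""Land-use attribution and activity budgets on a decoded survey.

Runs the whole pipeline on a small synthetic survey (decoding with the
reference model rather than refitting), then prints where each behavioural
state happens (land-use units) and the day/night activity budget.
"""

import pandas as pd

from herdhmm.pipeline import PipelineConfig, run_pipeline
from herdhmm.summaries import activity_budget

out = run_pipeline(PipelineConfig(
    out_dir="scratch/example_pipeline",
    seed=2,
    simulate=True,
    sim={"n_herds": 2, "n_days": 15, "transhumance_schedule": []},
    model_stage="fixture",
    budget_keys=("diel", "herd_type"),
))

annotated = pd.read_csv(out / "annotated.csv")
print("fixes per land-use unit:")
print(annotated["unit"].value_counts().to_string())

budget = activity_budget(annotated, keys=("diel", "herd_type"))
cols = [c for c in budget.columns if c.startswith("p_")]
print("\nactivity budget (proportion of fixes per state):")
print(budget[["diel", "herd_type", *cols, "total"]].round(3).to_string(index=False))
# Resident herds show a nearly pure resting state at night (tethering), and
# most fixes fall in the cultivated ring (bushfields) around the village.
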