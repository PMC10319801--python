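"""Exposure-risk scores: normalised petrel UD x normalised plastic grid,
summed and scaled by 10^6; monthly, seasonal, population, species and
all-species scopes with population-size and season-coverage weighting."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_score

cfg = run_config(__doc__)
stage_score(cfg)
res = cfg.paths()["results"]
pops = pd.read_csv(res / "population_scores.csv")
species = pd.read_csv(res / "species_scores.csv")
summary = pd.read_csv(res / "summary_scores.csv")
print("population scores (mean over tracked months):")
print(pops.to_string(index=False))
print("\nspecies scores (population-size weighted, breeding-only halved):")
print(species.to_string(index=False))
print("\n" + summary.to_string(index=False))
ref = summary.set_index("quantity").loc["uniform_plastic_reference", "value"]
above = pops[pops["score"] > ref]["population_id"].tolist()
print(f"\npopulations above the even-plastic reference ({ref:.1f}): {above}")
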