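"""Label each tracked month breeding or non-breeding from distance to the
colony, smooth to one season of each type, and reconcile against the
published breeding schedules."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_phenology

cfg = run_config(__doc__)
out = stage_phenology(cfg)
phen = pd.read_csv(out)
tracked = phen[phen["label"] != "untracked"]
print(tracked.groupby(["population_id", "label"]).size().unstack(fill_value=0))
overridden = tracked[tracked["label_source"] == "reconciled"]
if len(overridden):
    print("published labels overridden (birds absent from colony):")
    print(overridden[["population_id", "month", "min_colony_distance"]].to_string(index=False))
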