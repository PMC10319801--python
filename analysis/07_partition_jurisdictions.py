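"""Attribute the all-species exposure map to EEZs, the joint regime and
the high seas; link each population's exposure back to its breeding
country."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_partition

cfg = run_config(__doc__)
stage_partition(cfg)
res = cfg.paths()["results"]
shares = pd.read_csv(res / "jurisdiction_shares.csv")
print("all-species exposure by jurisdiction:")
print(
    shares.sort_values("fraction", ascending=False)[
        ["jurisdiction", "sovereign", "fraction"]
    ].to_string(index=False)
)
linkage = pd.read_csv(res / "breeding_country_linkage.csv")
print("\nshare of each population's exposure inside its own EEZ:")
print(linkage.to_string(index=False))
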