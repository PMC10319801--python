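"""Monthly kernel utilisation distributions per population: 200-km
Gaussian smoothing on a 10-km equal-area grid, 95% isopleth, land trim,
aggregation onto the global 1-degree grid."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_ud

cfg = run_config(__doc__)
out = stage_ud(cfg)
uds = pd.read_csv(out)
months = uds.groupby("population")["month"].nunique()
print("population-months with a UD (months with <5 pooled locations dropped):")
print(months.to_string())
print(f"mean occupied 1-degree cells per monthly UD: "
      f"{uds.groupby(['population','month']).size().mean():.0f}")
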