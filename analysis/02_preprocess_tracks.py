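"""Standardise and quality-filter the tracking data: equinox stripping for
geolocators, the >90 km/h speed filter, colony-attendance buffers, and
12-hourly regularisation of GPS/PTT tracks."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_preprocess

cfg = run_config(__doc__)
out = stage_preprocess(cfg)
raw = pd.read_csv(f"{cfg.outdir}/inputs/tracks.csv")
clean = pd.read_csv(out)
print(f"retained {len(clean)}/{len(raw)} locations ({len(clean)/len(raw):.1%})")
print(clean.groupby("population").size().to_string())
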