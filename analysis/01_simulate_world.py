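"""Generate the demo world: synthetic tracking data for three petrel
populations (GPS, PTT, GLS), three noisy plastic-model grids over a
lognormal hotspot field, a land mask and toy jurisdictions."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_simulate

cfg = run_config(__doc__)
files = stage_simulate(cfg)
tracks = pd.read_csv(files["tracks.csv"])
print(f"wrote {len(files)} input files to {cfg.outdir}/inputs")
print(
    f"tracking table: {len(tracks)} locations, "
    f"{tracks['individual_id'].nunique()} individuals, "
    f"{tracks['population'].nunique()} populations, "
    f"devices: {sorted(tracks['device'].unique())}"
)
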