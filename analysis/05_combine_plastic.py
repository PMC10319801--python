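"""Fuse the three plastic-model grids: per-cell geometric mean with
missing-model fallback, imputation of the known-bad 0-1W column, and
normalisation to unit sum."""

import pandas as pd

from common import run_config
from plastic_exposure.pipeline import stage_plastic

cfg = run_config(__doc__)
out = stage_plastic(cfg)
combined = pd.read_csv(out)
print(f"combined plastic layer: {len(combined)} estimated cells; "
      f"sum = {combined['density'].sum():.6f} (normalised)")
print(f"top cell holds {combined['density'].max():.2%} of global plastic mass")
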