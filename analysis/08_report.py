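"""Render the report: ranked species table, jurisdiction table, and the
square-root-scaled, percentile-capped all-species exposure map image."""

from common import run_config
from plastic_exposure.pipeline import make_report

cfg = run_config(__doc__)
report_dir = make_report(cfg)
print(f"report written to {report_dir}:")
for p in sorted(report_dir.iterdir()):
    print(f"  {p.name}")
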