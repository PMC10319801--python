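"""Shared argument handling for the numbered analysis drivers.

Every driver operates on the same run directory (default
``results/demo-run``) so the stages compose: run them in order, or run
any later stage after its predecessors.
"""

import argparse

from plastic_exposure.pipeline import RunConfig


def run_config(description: str) -> RunConfig:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", default="results/demo-run")
    args = parser.parse_args()
    return RunConfig(outdir=args.outdir, seed=args.seed)
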