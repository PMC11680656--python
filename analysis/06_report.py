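#!/usr/bin/env python
"""Summarize a completed run as markdown (flow, selection trace, HR tables)."""

import argparse

from alctraj.pipeline import make_report

parser = argparse.ArgumentParser()
parser.add_argument("--run", default="results/run")
args = parser.parse_args()

print(make_report(args.run))
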