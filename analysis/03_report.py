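#!/usr/bin/env python
"""Render the run report: cell counts, best-family tallies, star-annotated
comparison matrices, and the effect-size table with magnitude labels.

Writes results/report.md and prints the effect-size section.
"""

import argparse
from pathlib import Path

from mmspike.pipeline import summarize_run

parser = argparse.ArgumentParser()
parser.add_argument("--bundle", type=Path, default=Path("results/run"))
parser.add_argument("--out", type=Path, default=Path("results/report.md"))
args = parser.parse_args()

report = summarize_run(args.bundle)
args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(report)
print(f"report written to {args.out}\n")
section = report.split("## Effect sizes")[1].split("##")[0]
print("Effect sizes (ASD vs TD, TD control):" + section)
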