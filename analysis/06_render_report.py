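#!/usr/bin/env python
"""Render the human-readable markdown report for the pipeline run.

Top-ten tables with significance asterisks, lesion-frequency slice images
and the NIHSS-vs-mRS comparison, written to scratch/run/report.md and
mirrored to results/report.md.
"""

import shutil
from pathlib import Path

from lesionload import render_report

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    if not RUN_DIR.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    text = render_report(RUN_DIR)
    RESULTS.mkdir(exist_ok=True)
    shutil.copyfile(RUN_DIR / "report.md", RESULTS / "report.md")
    print(f"report rendered ({len(text.splitlines())} lines) -> {RESULTS / 'report.md'}")


if __name__ == "__main__":
    main()
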