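#!/usr/bin/env python
"""Compare the NIHSS and mRS correlation profiles (whole cohort).

For each delineation kind, collects the Wilcoxon signed-rank comparison of
the 122 paired correlation magnitudes computed by the pipeline, and writes
results/scale_comparison.tsv.  A small two-sided p indicates the NIHSS
profile differs systematically from the mRS profile — with the synthetic
outcome model, NIHSS tracks the lesion loads more faithfully.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    paths = sorted(RUN_DIR.glob("*/scale_comparison.tsv"))
    if not paths:
        raise SystemExit("run analysis/02_run_pipeline.py first")
    rows = []
    for p in paths:
        df = pd.read_csv(p, sep="\t")
        df.insert(0, "delineation", p.parent.name)
        rows.append(df)
    out = pd.concat(rows)
    RESULTS.mkdir(exist_ok=True)
    out.to_csv(RESULTS / "scale_comparison.tsv", sep="\t", index=False,
               lineterminator="\n", float_format="%.4g")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
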