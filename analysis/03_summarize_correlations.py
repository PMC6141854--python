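#!/usr/bin/env python
"""Summarize the correlation analysis: top-ten regions per delineation and split.

Collects the pipeline's correlation tables, writes one combined top-ten table
(results/top10_correlations.tsv) and a per-(kind, split, outcome) count of
bootstrap-significant features (results/significance_counts.tsv), and reports
where the designated outcome-driving regions ranked.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN_DIR = ROOT / "scratch" / "run"
RESULTS = ROOT / "results"


def main() -> None:
    if not RUN_DIR.exists():
        raise SystemExit("run analysis/02_run_pipeline.py first")
    top_rows, sig_rows = [], []
    for corr_path in sorted(RUN_DIR.glob("*/*/*/correlations.tsv")):
        outcome = corr_path.parent.name
        split = corr_path.parent.parent.name
        kind = corr_path.parent.parent.parent.name
        df = pd.read_csv(corr_path, sep="\t")
        sig_rows.append(
            {
                "delineation": kind,
                "split": split,
                "outcome": outcome,
                "n_features": len(df),
                "n_defined": int(df["r"].notna().sum()),
                "n_significant": int(df["significant"].sum()),
                "max_r": df["r"].max(),
            }
        )
        top = pd.read_csv(corr_path.parent / "top10.tsv", sep="\t")
        top.insert(0, "outcome", outcome)
        top.insert(0, "split", split)
        top.insert(0, "delineation", kind)
        top_rows.append(top)

    RESULTS.mkdir(exist_ok=True)
    pd.concat(top_rows).to_csv(RESULTS / "top10_correlations.tsv", sep="\t",
                               index=False, lineterminator="\n", float_format="%.4g")
    sig = pd.DataFrame(sig_rows)
    sig.to_csv(RESULTS / "significance_counts.tsv", sep="\t", index=False,
               lineterminator="\n", float_format="%.4g")
    print(sig.to_string(index=False))
    whole = sig[sig["split"] == "all"]
    print(f"\nhighest whole-cohort correlation: r = {whole['max_r'].max():.3f}")


if __name__ == "__main__":
    main()
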