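#!/usr/bin/env python
"""Calibration of the percentile-bootstrap confidence interval.

Simulates 500 bivariate-normal cohorts (true Pearson r = 0.5, n = 55), one
95% percentile interval from 1000 resamples each, and reports the empirical
coverage — the fraction of intervals containing the true correlation.
Writes results/bootstrap_coverage.tsv.
"""

from pathlib import Path

import pandas as pd

from lesionload.correlation_stats import bootstrap_coverage

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    coverage = bootstrap_coverage(true_r=0.5, n=55, n_boot=1000,
                                  n_replicates=500, level=0.95, seed=2026)
    df = pd.DataFrame(
        [{"true_r": 0.5, "n": 55, "n_boot": 1000, "n_replicates": 500,
          "nominal_level_pct": 95.0, "empirical_coverage_pct": coverage}]
    )
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "bootstrap_coverage.tsv", sep="\t", index=False, lineterminator="\n")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
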