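#!/usr/bin/env python
"""Run the full analysis pipeline on the simulated cohort.

For each delineation kind (follow-up segmentation, ADC < 600e-6 core,
Tmax > 6 s deficit, binarized prediction): compute per-region lesion loads,
split the cohort by revascularization success (TICI 2b-3 vs 0-2a), correlate
every load feature and the total volume with 3-month NIHSS and mRS
(percentile bootstrap, 1000 resamples), and compare the two outcome scales.
Outputs land under scratch/run/.
"""

from pathlib import Path

from lesionload import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "cohort"
RUN_DIR = ROOT / "scratch" / "run"

CONFIG = {
    "input_dir": str(DATA_DIR),
    "delineations": ["followup_segmentation", "adc_core", "tmax_deficit", "prediction"],
    "outcomes": ["nihss_3m", "mrs_3m"],
    "n_boot": 1000,
    "level": 0.95,
    "seed": 2026,
    "top_k": 10,
}


def main() -> None:
    if not (DATA_DIR / "cohort.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    out = run_pipeline(CONFIG, RUN_DIR)
    print(f"pipeline complete -> {out}")
    for kind in CONFIG["delineations"]:
        print(" ", kind, "->", sorted(p.name for p in (out / kind).iterdir()))


if __name__ == "__main__":
    main()
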