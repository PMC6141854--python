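"""End-to-end orchestration: simulate/ingest -> delineate -> loads -> split ->
correlate -> compare -> report.

A run consumes either a simulation block (the synthetic cohort is written to
the run's ``data/`` directory in the canonical layout) or an existing data
directory with the same layout::

    data/
      atlas_labels.nii.gz, atlas_regions.tsv, cohort.tsv
      volumes/<pid>_{followup,core,penumbra}.nii.gz
      volumes/<pid>_{adc,tmax,prediction}.nii.gz

Each downstream stage reads only files written by earlier stages, so any
stage's outputs can be deleted and reproduced exactly.  Results land in
``<run>/<delineation_kind>/<split>/<outcome>/``.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    CohortTable,
    read_atlas,
    read_cohort,
    read_mask,
    read_scalar_map,
    split_by_tici,
    write_mask,
    write_scalar_map,
)
from .delineation import (
    binarize_prediction,
    delineate_adc_core,
    delineate_tmax_deficit,
    lesion_frequency_map,
)
from .lesion_load import compute_load_matrix
from .correlation_stats import compare_profiles, correlate_features, rank_top
from .synthetic_cohort import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)

DELINEATION_KINDS = ("followup_segmentation", "adc_core", "tmax_deficit", "prediction")
SPLITS = ("all", "successful", "unsuccessful")
OUTCOMES = ("nihss_3m", "mrs_3m")


def _stage_seed(master_seed: int, *tags) -> int:
    """Deterministic sub-seed for a pipeline stage, stable across runs."""
    digest = hashlib.sha256(":".join([str(master_seed)] + [str(t) for t in tags]).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _write_config(config: dict, path: Path) -> None:
    text = yaml.safe_dump(config, sort_keys=True)
    path.write_text(text)


def _simulate_stage(config: dict, data_dir: Path) -> None:
    sim = SimulationConfig.from_dict(config.get("simulation", {}))
    logger.info("simulate: %d patients, seed %d", sim.n_patients, sim.master_seed)
    generate_cohort(sim, outdir=data_dir)


def _delineate_stage(data_dir: Path, run_dir: Path, kinds, cohort: CohortTable, grid, brain_mask) -> None:
    vdir = data_dir / "volumes"
    for kind in kinds:
        kdir = run_dir / kind / "masks"
        kdir.mkdir(parents=True, exist_ok=True)
        for pid in cohort.patient_ids:
            out = kdir / f"{pid}.nii.gz"
            if kind == "followup_segmentation":
                mask = read_mask(vdir / f"{pid}_followup.nii.gz", grid, pid, kind)
            elif kind == "adc_core":
                adc = read_scalar_map(vdir / f"{pid}_adc.nii.gz", grid, "adc")
                mask = delineate_adc_core(adc, brain_mask=brain_mask, patient_id=pid)
            elif kind == "tmax_deficit":
                tmax = read_scalar_map(vdir / f"{pid}_tmax.nii.gz", grid, "tmax")
                mask = delineate_tmax_deficit(tmax, brain_mask=brain_mask, patient_id=pid)
            elif kind == "prediction":
                prob = read_scalar_map(vdir / f"{pid}_prediction.nii.gz", grid, "probability")
                mask = binarize_prediction(prob, brain_mask=brain_mask, patient_id=pid)
            else:
                raise ValueError(f"unknown delineation kind {kind!r}")
            write_mask(mask, out)
        logger.info("delineate: %s done (%d masks)", kind, len(cohort))


def _analysis_stage(run_dir: Path, kinds, atlas, cohort: CohortTable, options: dict) -> None:
    successful, unsuccessful = split_by_tici(cohort)
    split_cohorts = {"all": cohort, "successful": successful, "unsuccessful": unsuccessful}
    name_map = dict(zip(atlas.regions["region_id"], atlas.regions["name"]))
    n_boot = int(options.get("n_boot", 1000))
    level = float(options.get("level", 0.95))
    seed = int(options.get("seed", 0))
    top_k = int(options.get("top_k", 10))
    outcomes = options.get("outcomes", list(OUTCOMES))

    for kind in kinds:
        kdir = run_dir / kind
        masks = [
            read_mask(kdir / "masks" / f"{pid}.nii.gz", atlas.grid, pid, kind)
            for pid in cohort.patient_ids
        ]
        loads_all = compute_load_matrix(masks, atlas, cohort)
        mask_by_pid = dict(zip(cohort.patient_ids, masks))
        all_tables = {}
        for split, sub in split_cohorts.items():
            if len(sub) == 0:
                logger.warning("split %r is empty for kind %s; skipped", split, kind)
                continue
            sdir = kdir / split
            sdir.mkdir(parents=True, exist_ok=True)
            loads = loads_all.subset(sub.patient_ids)
            loads.to_tsv(sdir / "loads.tsv", atlas)
            freq = lesion_frequency_map([mask_by_pid[pid] for pid in sub.patient_ids])
            write_scalar_map(freq, sdir / "frequency_map.nii.gz")
            if len(sub) < 2:
                logger.warning("split %r has < 2 patients; correlations skipped", split)
                continue
            for outcome in outcomes:
                odir = sdir / outcome
                odir.mkdir(exist_ok=True)
                table = correlate_features(
                    loads,
                    sub,
                    outcome,
                    n_boot=n_boot,
                    level=level,
                    seed=_stage_seed(seed, kind, split, outcome),
                    atlas_names=name_map,
                    cohort_tag=split,
                )
                table.to_tsv(odir / "correlations.tsv")
                top = rank_top(table, k=top_k)
                pd.DataFrame(
                    {
                        "rank": np.arange(1, len(top) + 1),
                        "feature_id": [str(t.feature_id) for t in top],
                        "name": [t.name for t in top],
                        "r": [t.r for t in top],
                        "significant": [t.significant for t in top],
                    }
                ).to_csv(odir / f"top{top_k}.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.6g")
                if split == "all":
                    all_tables[outcome] = table
        # first analysis step: NIHSS vs mRS correlation profiles on the whole
        # cohort, compared on correlation magnitudes (strength of association)
        if "nihss_3m" in all_tables and "mrs_3m" in all_tables:
            res = compare_profiles(
                {k: abs(v) for k, v in all_tables["nihss_3m"].r_profile().items()},
                {k: abs(v) for k, v in all_tables["mrs_3m"].r_profile().items()},
            )
            pd.DataFrame(
                [
                    {
                        "comparison": "nihss_3m_vs_mrs_3m",
                        "statistic": res.statistic,
                        "p_two_sided": res.p_value,
                        "n_pairs": res.n_pairs,
                        "exact": res.exact,
                        "degenerate": res.degenerate,
                    }
                ]
            ).to_csv(kdir / "scale_comparison.tsv", sep="\t", index=False, lineterminator="\n", float_format="%.6g")
        logger.info("analysis: %s done", kind)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Run the full pipeline from a config mapping (or YAML path).

    Config keys: ``simulation`` (SimulationConfig fields) or ``input_dir``;
    ``delineations`` (subset of the four kinds); ``outcomes``; ``n_boot``;
    ``level``; ``seed``; ``top_k``.  Returns the run directory.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    run_dir = Path(outdir)
    run_dir.mkdir(parents=True, exist_ok=True)

    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lesionload")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg_text = yaml.safe_dump(config, sort_keys=True)
        logger.info("config hash %s", hashlib.sha256(cfg_text.encode()).hexdigest()[:16])
        logger.info("numpy %s, pandas %s", np.__version__, pd.__version__)
        _write_config(config, run_dir / "config_used.yaml")

        if "simulation" in config:
            data_dir = run_dir / "data"
            if not (data_dir / "cohort.tsv").exists():
                _simulate_stage(config, data_dir)
        elif "input_dir" in config:
            data_dir = Path(config["input_dir"])
        else:
            raise ValueError("config needs a 'simulation' block or an 'input_dir'")

        atlas = read_atlas(data_dir / "atlas_labels.nii.gz", data_dir / "atlas_regions.tsv")
        cohort = read_cohort(data_dir / "cohort.tsv")
        kinds = config.get("delineations", list(DELINEATION_KINDS))
        unknown = set(kinds) - set(DELINEATION_KINDS)
        if unknown:
            raise ValueError(f"unknown delineation kinds: {sorted(unknown)}")
        brain = atlas.brain_mask()

        _delineate_stage(data_dir, run_dir, kinds, cohort, atlas.grid, brain)
        _analysis_stage(run_dir, kinds, atlas, cohort, config)
        logger.info("pipeline complete: %s", run_dir)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return run_dir


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _top_table_md(df: pd.DataFrame) -> list[str]:
    lines = ["| rank | region | r | significant |", "|---|---|---|---|"]
    for _, row in df.iterrows():
        star = "*" if bool(row["significant"]) else ""
        lines.append(f"| {int(row['rank'])} | {row['name']} | {row['r']:.3f} | {star} |")
    return lines


def render_report(run_dir: str | Path, with_images: bool = True) -> str:
    """Render a markdown summary of a completed run (written to report.md).

    Per delineation kind and cohort split: the top-correlating features with
    significance asterisks and a mid-axial slice of the lesion-frequency
    map; plus the whole-cohort NIHSS-vs-mRS profile comparison.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "config_used.yaml").exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (config_used.yaml missing)")
    kinds = [p.parent.name for p in sorted(run_dir.glob("*/masks"))]
    if not kinds:
        raise FileNotFoundError(f"{run_dir}: no delineation outputs found")
    lines = ["# Lesion-load correlation report", ""]
    for kind in kinds:
        kdir = run_dir / kind
        lines += [f"## {kind}", ""]
        comparison = kdir / "scale_comparison.tsv"
        if comparison.exists():
            row = pd.read_csv(comparison, sep="\t").iloc[0]
            tag = " (degenerate)" if bool(row["degenerate"]) else ""
            lines += [
                f"Whole-cohort NIHSS vs mRS correlation profiles: Wilcoxon signed-rank "
                f"W+ = {row['statistic']:.1f}, two-sided p = {row['p_two_sided']:.3g} "
                f"over {int(row['n_pairs'])} paired features{tag}.",
                "",
            ]
        for sdir in sorted(p for p in kdir.iterdir() if p.is_dir() and p.name != "masks"):
            split = sdir.name
            lines += [f"### {split}", ""]
            tops = sorted(sdir.glob("*/top*.tsv"))
            if not tops:
                lines += ["no estimable features", ""]
            for top_path in tops:
                outcome = top_path.parent.name
                df = pd.read_csv(top_path, sep="\t")
                lines += [f"Top correlating features vs {outcome} (* = bootstrap-significant):", ""]
                if df.empty:
                    lines += ["no estimable features", ""]
                else:
                    lines += _top_table_md(df) + [""]
            freq_path = sdir / "frequency_map.nii.gz"
            if freq_path.exists() and with_images:
                png = sdir / "frequency_map_axial.png"
                _save_mid_slice(freq_path, png)
                lines += [f"![lesion frequency, {kind}/{split}]({png.relative_to(run_dir)})", ""]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text


def _save_mid_slice(nifti_path: Path, out_png: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    data = np.asanyarray(nib.load(str(nifti_path)).dataobj)
    sl = data[:, :, data.shape[2] // 2]
    fig, ax = plt.subplots(figsize=(3, 3))
    im = ax.imshow(sl.T, origin="lower", cmap="hot", vmin=0.0, vmax=max(1e-9, float(sl.max())))
    ax.set_axis_off()
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.savefig(out_png, dpi=100, bbox_inches="tight")
    plt.close(fig)
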