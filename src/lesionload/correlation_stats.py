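"""Correlation of lesion-load features with clinical outcome.

Each feature (regional load or total lesion volume) is related to the
3-month outcome score by a Pearson correlation.  Significance follows a
nonparametric bootstrap: patients are resampled with replacement, the
correlation recomputed per resample, and the 95% percentile interval of the
resampled correlations taken; a correlation is significant exactly when that
interval excludes zero.  No multiple-comparison correction is applied — the
analysis is exploratory and the region ranking is the object of interest.

Sparse loads make zero-variance resamples (no lesioned patient drawn) a real
possibility; such resamples yield an undefined correlation and are dropped
from the percentile computation, with counts reported.  If more than half
the resamples are dropped the interval is declared non-estimable.

Two correlation profiles (e.g. the NIHSS and mRS profiles over the same
features) are compared with a Wilcoxon signed-rank test: exact (sign-flip
enumeration via dynamic programming) for up to 25 retained pairs, normal
approximation with continuity correction beyond that.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CohortTable
from .lesion_load import LoadMatrix

DEFAULT_N_BOOT = 1000
DEFAULT_LEVEL = 0.95
#: Bootstrap CI is non-estimable if more than this fraction of resamples is dropped.
MAX_DROP_FRACTION = 0.5
#: Pair count up to which the Wilcoxon null distribution is enumerated exactly.
WILCOXON_EXACT_MAX_N = 25


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (= undefined) if either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D and equal length, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def _resample_correlations(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Pearson r for each row of resample indices; NaN where variance vanishes."""
    bx = x[idx]
    by = y[idx]
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    sx = np.sqrt((bx * bx).sum(axis=1))
    sy = np.sqrt((by * by).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (bx * by).sum(axis=1) / denom
    r[denom == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


@dataclass(frozen=True)
class BootstrapCI:
    ci_low: float
    ci_high: float
    n_used: int
    n_dropped: int

    @property
    def estimable(self) -> bool:
        return not (np.isnan(self.ci_low) or np.isnan(self.ci_high))


def bootstrap_ci(
    x,
    y,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed=None,
    rng: np.random.Generator | None = None,
) -> BootstrapCI:
    """Percentile bootstrap interval for the Pearson correlation of (x, y).

    ``n_boot`` resamples of the n patient pairs are drawn jointly with
    replacement; undefined resample correlations are dropped (and counted);
    the interval is the empirical (1-level)/2 and (1+level)/2 quantiles
    (linear interpolation) of the retained correlations.  Non-estimable
    (NaN bounds) if more than half the resamples were dropped.  A seed (or
    an explicit generator) is mandatory for reproducibility.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or generator) is required for the bootstrap")
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    r = _resample_correlations(x, y, idx)
    kept = r[~np.isnan(r)]
    n_dropped = n_boot - kept.size
    if kept.size == 0 or n_dropped > MAX_DROP_FRACTION * n_boot:
        return BootstrapCI(float("nan"), float("nan"), int(kept.size), int(n_dropped))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(kept, [alpha, 1.0 - alpha])
    return BootstrapCI(float(lo), float(hi), int(kept.size), int(n_dropped))


def bootstrap_coverage(
    true_r: float = 0.5,
    n: int = 55,
    n_boot: int = DEFAULT_N_BOOT,
    n_replicates: int = 500,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> float:
    """Empirical coverage (%) of the percentile bootstrap CI for Pearson's r.

    Draws ``n_replicates`` bivariate-normal samples of size ``n`` with true
    correlation ``true_r``; for each, builds the percentile interval from
    ``n_boot`` resamples and checks whether it contains ``true_r``.  A
    calibration check of the interval the correlation analysis relies on.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        z = rng.standard_normal((n, 2))
        x = z[:, 0]
        y = true_r * z[:, 0] + np.sqrt(1.0 - true_r**2) * z[:, 1]
        ci = bootstrap_ci(x, y, n_boot=n_boot, level=level, rng=rng)
        if ci.estimable and ci.ci_low <= true_r <= ci.ci_high:
            hits += 1
    return 100.0 * hits / n_replicates


def significance(ci_low: float, ci_high: float) -> bool:
    """Zero-exclusion rule on the closed interval: significant iff 0 is outside."""
    if np.isnan(ci_low) or np.isnan(ci_high):
        return False
    return bool(ci_low > 0.0 or ci_high < 0.0)


@dataclass
class CorrelationRecord:
    feature_id: object  # region id (int) or the string 'total_volume'
    name: str
    r: float  # NaN = undefined
    ci_low: float
    ci_high: float
    significant: bool
    n_boot_used: int
    n_boot_dropped: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)


@dataclass
class CorrelationTable:
    records: list[CorrelationRecord]
    outcome_name: str
    cohort_tag: str = "all"
    delineation_kind: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, feature_id) -> CorrelationRecord:
        for rec in self.records:
            if rec.feature_id == feature_id:
                return rec
        raise KeyError(feature_id)

    def r_profile(self) -> dict:
        """Mapping feature_id -> r (NaN where undefined)."""
        return {rec.feature_id: rec.r for rec in self.records}

    def to_frame(self) -> pd.DataFrame:
        ranked = {rec.feature_id: i + 1 for i, rec in enumerate(rank_top(self, k=len(self)))}
        return pd.DataFrame(
            {
                "feature_id": [str(r.feature_id) for r in self.records],
                "name": [r.name for r in self.records],
                "r": [r.r for r in self.records],
                "ci_low": [r.ci_low for r in self.records],
                "ci_high": [r.ci_high for r in self.records],
                "significant": [r.significant for r in self.records],
                "n_boot_used": [r.n_boot_used for r in self.records],
                "n_boot_dropped": [r.n_boot_dropped for r in self.records],
                "rank": [ranked.get(r.feature_id, np.nan) for r in self.records],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.6g")


def feature_rng(master_seed: int, feature_id) -> np.random.Generator:
    """Independent per-feature random stream, stable under feature add/remove.

    The stream is keyed by a hash of the feature id, so the bootstrap for one
    feature never depends on which other features are present or their order.
    """
    digest = hashlib.sha256(str(feature_id).encode("utf-8")).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


def correlate_features(
    loads: LoadMatrix,
    cohort: CohortTable,
    outcome: str,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
    atlas_names: dict | None = None,
    cohort_tag: str = "all",
) -> CorrelationTable:
    """Correlate every load feature (plus total volume) with an outcome score.

    Rows of ``loads`` must align with ``cohort`` (same patient ids, same
    order).  With ``n_boot=0`` only the point correlations are computed and
    every record is flagged insignificant with an undefined interval.
    """
    if loads.row_ids != cohort.patient_ids:
        raise ValueError("load-matrix rows do not align with the cohort table")
    y = cohort.outcome(outcome)
    names = atlas_names or {}
    records = []
    feature_ids = list(loads.column_ids) + ["total_volume"]
    for fid in feature_ids:
        x = loads.feature(fid)
        r = pearson_r(x, y)
        if n_boot > 0 and not np.isnan(r):
            ci = bootstrap_ci(x, y, n_boot=n_boot, level=level, rng=feature_rng(seed, fid))
        else:
            ci = BootstrapCI(float("nan"), float("nan"), 0, n_boot if not np.isnan(r) else n_boot)
        records.append(
            CorrelationRecord(
                feature_id=fid,
                name=names.get(fid, "total_volume" if fid == "total_volume" else f"region_{fid}"),
                r=r,
                ci_low=ci.ci_low,
                ci_high=ci.ci_high,
                significant=significance(ci.ci_low, ci.ci_high),
                n_boot_used=ci.n_used,
                n_boot_dropped=ci.n_dropped,
            )
        )
    return CorrelationTable(
        records=records,
        outcome_name=outcome,
        cohort_tag=cohort_tag,
        delineation_kind=loads.delineation_kind,
    )


def _rank_key(rec: CorrelationRecord):
    # ties broken by ascending region id; total volume sorts after the regions
    if rec.feature_id == "total_volume":
        return (-rec.r, 1, 0)
    return (-rec.r, 0, int(rec.feature_id))


def rank_top(table: CorrelationTable, k: int = 10) -> list[CorrelationRecord]:
    """The k features with largest correlation, undefined excluded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    defined = [rec for rec in table if rec.defined]
    return sorted(defined, key=_rank_key)[:k]


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # sum of positive-signed ranks (W+)
    p_value: float
    n_pairs: int  # retained (nonzero-difference) pairs
    exact: bool
    degenerate: bool = False


def _signed_rank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Exact pmf of twice the positive-rank sum under random sign flips.

    ``ranks2`` are the (mid)ranks doubled so ties give integers.  The pmf is
    built by dynamic programming over the 2^n equiprobable sign assignments.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = 0.5 * pmf.copy()
        nxt[r:] += 0.5 * pmf[: total + 1 - r]
        pmf = nxt
    return pmf


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  For up to 25 retained pairs the null
    distribution of the rank sum is enumerated exactly over all sign
    assignments (midranks for tied magnitudes); otherwise the normal
    approximation with continuity and tie correction is used.  With no
    nonzero difference the result is degenerate: statistic 0, p = 1.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n < 1:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WILCOXON_EXACT_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        pmf = _signed_rank_pmf(ranks2)
        w2 = int(round(2.0 * w_plus))
        cdf = float(pmf[: w2 + 1].sum())
        sf = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(w_plus, p, n, exact=True)
    # large-sample branch: scipy's normal approximation with continuity correction
    res = stats.wilcoxon(d, correction=True, alternative="two-sided", method="approx")
    return WilcoxonResult(w_plus, float(res.pvalue), n, exact=False)


def compare_profiles(
    r_a: Sequence[float] | dict, r_b: Sequence[float] | dict
) -> WilcoxonResult:
    """Wilcoxon signed-rank comparison of two correlation profiles.

    The profiles are paired over the same feature set (dicts are aligned by
    key); pairs where either correlation is undefined are excluded.
    """
    if isinstance(r_a, dict) or isinstance(r_b, dict):
        if not (isinstance(r_a, dict) and isinstance(r_b, dict)):
            raise ValueError("pass either two dicts or two sequences")
        keys = [k for k in r_a if k in r_b]
        a = np.array([r_a[k] for k in keys], dtype=float)
        b = np.array([r_b[k] for k in keys], dtype=float)
    else:
        a = np.asarray(r_a, dtype=float)
        b = np.asarray(r_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("profiles must be paired over the same feature set")
    ok = ~(np.isnan(a) | np.isnan(b))
    return wilcoxon_signed_rank(a[ok] - b[ok])
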