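"""Set-overlap and interval-proximity enrichment with Fisher's exact
tests, percentile-bootstrap confidence intervals, and the sex-split
stability check.

Enrichment always compares a target CpG set (e.g. hvCpGs) against a
comparator set (distribution-matched controls, mQTL-matched controls, or
the array background) for membership in a feature (a published CpG set or
proximity to genomic intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import InputError, MethylationDataset, ProbeAnnotation
from .detect import top_variance_flags, dataset_variances

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAPS = 1000


@dataclass
class EnrichmentResult:
    """2x2 enrichment of a target vs comparator set in a feature.

    ``odds_ratio`` is the sample (cross-product) OR, infinite when a zero
    cell makes it so; ``odds_ratio_haldane`` applies the 0.5 continuity
    correction to every cell when any cell is zero.  ``fold`` is the ratio
    of in-feature proportions.  ``p`` is the two-sided Fisher's exact
    p-value.  Bootstrap CI bounds are attached when requested.
    """

    table: np.ndarray
    odds_ratio: float
    odds_ratio_haldane: float
    p: float
    fold: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def as_dict(self) -> dict:
        a, b = self.table[0]
        c, d = self.table[1]
        return {
            "target_in": int(a), "target_out": int(b),
            "comparator_in": int(c), "comparator_out": int(d),
            "odds_ratio": self.odds_ratio, "odds_ratio_haldane": self.odds_ratio_haldane,
            "p": self.p, "fold": self.fold, "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def _fisher_from_table(table: np.ndarray) -> EnrichmentResult:
    a, b = table[0]
    c, d = table[1]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    if min(a, b, c, d) == 0:
        hald = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        hald = odds
    prop_t = a / (a + b) if a + b else np.nan
    prop_c = c / (c + d) if c + d else np.nan
    fold = np.inf if prop_c == 0 and prop_t > 0 else (prop_t / prop_c if prop_c else np.nan)
    return EnrichmentResult(table=table, odds_ratio=float(odds), odds_ratio_haldane=float(hald),
                            p=float(p), fold=float(fold))


def fisher_enrichment(target: Iterable[str], comparator: Iterable[str], feature: Iterable[str]) -> EnrichmentResult:
    """Two-sided Fisher's exact enrichment of ``target`` vs ``comparator``
    for membership in ``feature``.  The sets ``target`` and ``comparator``
    must be disjoint and non-empty."""
    t, c, f = set(target), set(comparator), set(feature)
    if not t or not c:
        raise InputError("target and comparator must be non-empty")
    if t & c:
        raise InputError("target and comparator must be disjoint")
    table = np.array(
        [[len(t & f), len(t - f)], [len(c & f), len(c - f)]], dtype=np.int64
    )
    return _fisher_from_table(table)


def nearest_interval_distance(
    annotation: ProbeAnnotation, cpgs: Iterable[str], intervals: pd.DataFrame
) -> pd.Series:
    """Distance in bp from each CpG to the nearest feature interval.

    ``intervals`` is BED-style (``chrom``, ``start``, ``end``; 0-based,
    half-open); annotation positions are 1-based.  A CpG inside an
    interval has distance 0; CpGs on chromosomes without intervals get
    +inf.  Chromosome names present in the track but absent from the
    annotation (or vice versa with no overlap at all) raise an error.
    """
    pos = annotation.positions(pd.Index(sorted(set(cpgs))))
    track_chroms = set(intervals["chrom"]) if len(intervals) else set()
    if len(intervals) and not (track_chroms & set(pos["chrom"])):
        raise InputError(
            f"no shared chromosomes between annotation and track: {sorted(track_chroms)[:5]}"
        )
    out = pd.Series(np.inf, index=pos.index)
    for chrom, sub in pos.groupby("chrom", sort=False):
        iv = intervals[intervals["chrom"] == chrom]
        if iv.empty:
            continue
        starts = iv["start"].to_numpy(dtype=np.int64)
        ends = iv["end"].to_numpy(dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        p0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        # distance to each interval's nearest edge, minimised with a sweep
        # over (sorted) intervals; tracks are small so O(n_cpg * n_iv) is fine
        d = np.full(len(p0), np.inf)
        for s, e in zip(starts, ends):
            inside = (p0 >= s) & (p0 < e)
            dist = np.where(inside, 0, np.where(p0 < s, s - p0, p0 - (e - 1)))
            d = np.minimum(d, dist)
        out.loc[sub.index] = d
    return out


def proximity_enrichment(
    cpgs: Iterable[str],
    comparator: Iterable[str],
    annotation: ProbeAnnotation,
    intervals: pd.DataFrame,
    distances: Sequence[int] = (1000, 5000, 10_000),
) -> pd.DataFrame:
    """Per-threshold interval-proximity enrichment vs a comparator set.

    A CpG is proximal at threshold x when it lies within x bp of any
    interval (0 inside).  Returns one row per threshold with proportions
    and the Fisher enrichment; proportions are non-decreasing in x.
    """
    t = sorted(set(cpgs))
    c = sorted(set(comparator))
    d_t = nearest_interval_distance(annotation, t, intervals)
    d_c = nearest_interval_distance(annotation, c, intervals)
    rows = []
    for x in distances:
        feat = set(d_t.index[d_t <= x]) | set(d_c.index[d_c <= x])
        res = fisher_enrichment(t, c, feat)
        rec = res.as_dict()
        rec["distance_bp"] = int(x)
        rec["prop_target"] = float((d_t <= x).mean())
        rec["prop_comparator"] = float((d_c <= x).mean())
        rows.append(rec)
    return pd.DataFrame(rows)


def bootstrap_ci(
    statistic: Callable,
    data: Sequence,
    b: int = DEFAULT_BOOTSTRAPS,
    level: float = 0.95,
    seed: int = 0,
) -> tuple:
    """Percentile bootstrap CI for ``statistic(data)``.

    Resamples the units of ``data`` (CpGs, typically) with replacement
    ``b`` times; deterministic for a given seed.  A constant statistic
    yields a zero-width interval (logged).
    """
    if b < 100:
        raise InputError("need at least 100 bootstrap samples")
    data = np.asarray(data)  # numeric vector or id array; resampled by index
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(data)
    vals = np.array([statistic(data[rng.integers(0, n, n)]) for _ in range(b)], dtype=float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    if lo == hi:
        logger.info("bootstrap_ci: degenerate statistic, zero-width interval")
    return float(lo), float(hi)


def sex_split_stability(
    datasets: Iterable[MethylationDataset],
    hvcpgs: Iterable[str],
    min_n: int = 80,
    top_pct: float = 5.0,
    balance_min_fraction: float = 0.4,
) -> dict:
    """Proportion of hvCpGs in the top-variance tier of a single-sex split.

    Datasets qualify when both sexes are present, each makes up at least
    ``balance_min_fraction`` of samples, and n > ``min_n``.  Each
    qualifying dataset is split into male-only and female-only
    sub-datasets; top-``top_pct``-% variance flags are recomputed per
    sub-dataset, and the headline value is the proportion of hvCpGs
    flagged in at least one sub-dataset overall.
    """
    hv = pd.Index(sorted(set(hvcpgs)))
    detail: List[dict] = []
    flagged_any = pd.Series(False, index=hv)
    n_qualifying = 0
    for ds in datasets:
        if "sex" not in ds.covariates.columns or ds.n_samples <= min_n:
            continue
        sex = ds.covariates.loc[ds.beta.columns, "sex"]
        counts = sex.value_counts()
        if len(counts) < 2 or counts.min() / ds.n_samples < balance_min_fraction:
            continue
        n_qualifying += 1
        for level in ("male", "female"):
            cols = sex.index[sex == level]
            sub = MethylationDataset(
                dataset_id=f"{ds.dataset_id}_{level}",
                beta=ds.beta[cols],
                covariates=ds.covariates.loc[cols],
            )
            flags = top_variance_flags(dataset_variances(sub), top_pct)
            on_hv = flags.reindex(hv).fillna(False).astype(bool)
            flagged_any |= on_hv
            detail.append(
                {"dataset": ds.dataset_id, "sex": level,
                 "n_samples": len(cols), "n_hv_flagged": int(on_hv.sum())}
            )
    if n_qualifying == 0:
        raise InputError(f"no dataset with both sexes, balance and n > {min_n}")
    proportion = float(flagged_any.mean()) if len(hv) else np.nan
    return {"proportion": proportion, "per_dataset": pd.DataFrame(detail),
            "n_qualifying_datasets": n_qualifying}


def set_overlap_report(
    target: Iterable[str],
    published_sets: Dict[str, Iterable[str]],
    comparator: Iterable[str],
    background: Optional[Iterable[str]] = None,
    trait_min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Fisher enrichment of the target vs comparator in each published set.

    Published sets are first restricted to the array ``background`` (when
    given); sets overlapping fewer than ``trait_min_fraction`` of the
    target are excluded.  Benjamini-Hochberg q-values are appended across
    the tested sets alongside the raw p-values.
    """
    t = set(target)
    rows = []
    for name, ids in sorted(published_sets.items()):
        f = set(ids)
        if background is not None:
            f &= set(background)
        if len(t & f) < trait_min_fraction * len(t):
            logger.info("set %s excluded by the %.0f%% overlap filter", name, 100 * trait_min_fraction)
            continue
        res = fisher_enrichment(t, comparator, f)
        rec = res.as_dict()
        rec["set"] = name
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.set_index("set")
    return out
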