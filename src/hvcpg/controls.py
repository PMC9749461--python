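"""Distribution-matched and mQTL-matched control CpG sets, and mQTL
variance-explained summaries.

Distribution matching pairs each hvCpG with the background CpG whose Beta
distribution it is hardest to distinguish from (greatest two-sided
Kolmogorov-Smirnov p-value, required > 0.1), drawing controls without
replacement so no control serves two hvCpGs.  mQTL matching pairs each
hvCpG with a non-hvCpG reported in an mQTL summary table with the same
number of associations, closest mean variance explained, and at least the
same dataset coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .core import InputError, MethylationDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MQTLRecord:
    """One SNP-CpG association from an mQTL summary table.

    ``beta_effect`` is the per-allele effect size on (standardised)
    methylation; ``kind`` is ``"cis"`` or ``"trans"``.
    """

    cpg: str
    snp: str
    beta_effect: float
    maf: float
    kind: str = "cis"
    p: float = 1e-9

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise InputError(f"{self.cpg}/{self.snp}: MAF must be in (0, 0.5]")
        if not (0 < self.p <= 1):
            raise InputError(f"{self.cpg}/{self.snp}: p must be in (0, 1]")


@dataclass
class ControlMatch:
    """Result of a matching run: ``pairs`` (hvcpg -> control, stat) and the
    hvCpGs for which no qualifying control existed."""

    pairs: pd.DataFrame  # columns: hvcpg, control, stat
    unmatched: list

    @property
    def controls(self) -> pd.Index:
        return pd.Index(self.pairs["control"])


def _ks_d_one_vs_many(a_sorted: np.ndarray, b_sorted: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic between one sorted sample and each row of a
    sorted matrix, evaluated at every jump point of either ECDF."""
    n = a_sorted.size
    k, m = b_sorted.shape
    flat = b_sorted.ravel()
    right = np.searchsorted(a_sorted, flat, side="right").reshape(k, m) / n
    left = np.searchsorted(a_sorted, flat, side="left").reshape(k, m) / n
    jm = np.arange(1, m + 1) / m
    d = np.maximum(np.abs(right - jm), np.abs(left - (jm - 1.0 / m)))
    return d.max(axis=1)


def _ks_asymp_p(d: np.ndarray, n: int, m) -> np.ndarray:
    en = np.sqrt(n * np.asarray(m, dtype=float) / (n + np.asarray(m, dtype=float)))
    return stats.kstwobign.sf((en + 0.12 + 0.11 / en) * d)


def ks_match_controls(
    hvcpgs: Iterable[str],
    background: Iterable[str],
    reference_dataset: MethylationDataset,
    min_p: float = 0.1,
    prefilter: bool = True,
    prefilter_mean_window: float = 0.08,
    prefilter_sd_window: float = 0.06,
) -> ControlMatch:
    """Match each hvCpG to a distribution-similar background CpG.

    hvCpGs are processed in sorted-id order; for each, the background CpG
    with the greatest two-sided KS p-value against the hvCpG's Beta values
    is selected if p > ``min_p`` and removed from the pool (matching is
    injective).  When every retained probe has the same number of observed
    values the greatest-p candidate equals the smallest-D candidate, which
    is what the vectorised search uses; the winning pair's p-value is then
    recomputed with :func:`scipy.stats.ks_2samp`.

    A (mean, sd) pre-filter window narrows the candidate pool for speed;
    if no candidate inside the window qualifies, the full pool is scanned.
    """
    beta = reference_dataset.beta
    hv_ids = sorted(set(hvcpgs) & set(beta.index))
    bg_ids = sorted((set(background) - set(hvcpgs)) & set(beta.index))
    if not bg_ids:
        raise InputError("empty background pool")

    bg_vals = {c: np.sort(beta.loc[c].dropna().to_numpy()) for c in bg_ids}
    bg_ids = [c for c in bg_ids if bg_vals[c].size >= 2]
    bg_mean = np.array([bg_vals[c].mean() for c in bg_ids])
    bg_sd = np.array([bg_vals[c].std() for c in bg_ids])
    bg_n = np.array([bg_vals[c].size for c in bg_ids])
    available = np.ones(len(bg_ids), dtype=bool)
    uniform_n = bg_n.min() == bg_n.max()

    pairs, unmatched = [], []
    for hv in hv_ids:
        a = np.sort(beta.loc[hv].dropna().to_numpy())
        if a.size < 2:
            unmatched.append(hv)
            continue

        def best_in(cand_idx: np.ndarray):
            if cand_idx.size == 0:
                return None
            if uniform_n:
                mat = np.stack([bg_vals[bg_ids[ci]] for ci in cand_idx])
                d = _ks_d_one_vs_many(a, mat)
            else:
                d = np.array(
                    [_ks_d_one_vs_many(a, bg_vals[bg_ids[ci]][None, :])[0] for ci in cand_idx]
                )
            p = _ks_asymp_p(d, a.size, bg_n[cand_idx])
            order = np.lexsort((cand_idx, -p))  # max p, ties by candidate order
            return cand_idx[order[0]]

        chosen = None
        if prefilter:
            window = (
                (np.abs(bg_mean - a.mean()) <= prefilter_mean_window)
                & (np.abs(bg_sd - a.std()) <= prefilter_sd_window)
                & available
            )
            cand = best_in(np.flatnonzero(window))
            if cand is not None:
                p_exact = stats.ks_2samp(a, bg_vals[bg_ids[cand]]).pvalue
                if p_exact > min_p:
                    chosen = (cand, p_exact)
        if chosen is None:
            cand = best_in(np.flatnonzero(available))
            if cand is not None:
                p_exact = stats.ks_2samp(a, bg_vals[bg_ids[cand]]).pvalue
                if p_exact > min_p:
                    chosen = (cand, p_exact)

        if chosen is None:
            unmatched.append(hv)
        else:
            ci, p_exact = chosen
            available[ci] = False
            pairs.append({"hvcpg": hv, "control": bg_ids[ci], "stat": p_exact})

    logger.info("KS matching: %d/%d hvCpGs matched (min_p=%g)", len(pairs), len(hv_ids), min_p)
    return ControlMatch(
        pairs=pd.DataFrame(pairs, columns=["hvcpg", "control", "stat"]), unmatched=unmatched
    )


def mqtl_variance_explained(record: MQTLRecord) -> float:
    """Fraction of methylation variance attributable to one mQTL:
    2 * beta^2 * MAF * (1 - MAF), assuming variance-standardised
    methylation and Hardy-Weinberg genotype frequencies."""
    return 2.0 * record.beta_effect**2 * record.maf * (1.0 - record.maf)


def mean_variance_explained(records: Iterable[MQTLRecord]) -> pd.Series:
    """Per-CpG arithmetic mean of variance explained across its mQTLs."""
    acc: dict = {}
    for r in records:
        acc.setdefault(r.cpg, []).append(mqtl_variance_explained(r))
    out = pd.Series({c: float(np.mean(v)) for c, v in acc.items()}, dtype=float)
    out.index.name = "cpg"
    return out.sort_index()


def filter_mqtl_significance(
    table: pd.DataFrame, cis_p: float = 1e-8, trans_p: float = 1e-14
) -> pd.DataFrame:
    """Row-filter an mQTL table at the cis/trans significance thresholds."""
    keep = np.where(table["kind"] == "cis", table["p"] < cis_p, table["p"] < trans_p)
    return table.loc[keep].reset_index(drop=True)


def mqtl_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG summary of an mQTL table: ``n_assoc`` and
    ``mean_var_explained`` (2*beta^2*MAF*(1-MAF) averaged over records)."""
    ve = 2.0 * table["beta"].astype(float) ** 2 * table["maf"] * (1 - table["maf"])
    out = pd.DataFrame({"cpg": table["cpg"], "ve": ve}).groupby("cpg")["ve"].agg(["size", "mean"])
    out.columns = ["n_assoc", "mean_var_explained"]
    return out


def mqtl_match_controls(
    hvcpgs: Iterable[str],
    summaries: pd.DataFrame,
    tolerance: float = 0.005,
) -> ControlMatch:
    """Match hvCpGs to mQTL-profile-similar controls without replacement.

    ``summaries`` is indexed by CpG with columns ``n_assoc``,
    ``mean_var_explained`` and ``n_datasets_covered``.  A candidate is
    eligible for an hvCpG when it has (i) the identical association count,
    (ii) |difference in mean variance explained| <= ``tolerance`` and
    (iii) coverage in at least as many datasets; the nearest eligible
    candidate by variance explained wins (ties broken by id).
    """
    hv_ids = sorted(set(hvcpgs) & set(summaries.index))
    pool = summaries.drop(index=hv_ids, errors="ignore").sort_index()
    taken: set = set()
    pairs, unmatched = [], []
    for hv in hv_ids:
        row = summaries.loc[hv]
        elig = pool[
            (pool["n_assoc"] == row["n_assoc"])
            & (pool["n_datasets_covered"] >= row["n_datasets_covered"])
            & (~pool.index.isin(taken))
        ]
        if elig.empty:
            unmatched.append(hv)
            continue
        delta = (elig["mean_var_explained"] - row["mean_var_explained"]).abs()
        best = delta.sort_values(kind="stable").index[0]
        if delta[best] > tolerance:
            unmatched.append(hv)
            continue
        taken.add(best)
        pairs.append({"hvcpg": hv, "control": best, "stat": float(delta[best])})
    logger.info("mQTL matching: %d/%d hvCpGs matched", len(pairs), len(hv_ids))
    return ControlMatch(
        pairs=pd.DataFrame(pairs, columns=["hvcpg", "control", "stat"]), unmatched=unmatched
    )
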