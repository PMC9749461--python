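"""Co-methylation decay with genomic distance, hvCpG clusters at a 4-kb
gap, and de-clustering.

Clusters are maximal single-linkage chains of CpGs on one chromosome in
which consecutive members are at most ``gap`` bp apart (default 4000 bp,
the distance at which pairwise co-methylation levels out).  De-clustering
keeps one random member per cluster plus all singletons, yielding a set
with minimum same-chromosome spacing > gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import InputError, MethylationDataset, ProbeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_GAP_BP = 4000
MIN_SAMPLES_FOR_DECAY = 100


@dataclass
class ClusterSet:
    """Partition of a CpG set into clusters (>= 2 members, position-sorted)
    and singletons."""

    clusters: List[List[str]]
    singletons: List[str]
    gap: int = DEFAULT_GAP_BP

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    def all_members(self) -> set:
        out = set(self.singletons)
        for c in self.clusters:
            out.update(c)
        return out


def build_clusters(cpgs: Iterable[str], annotation: ProbeAnnotation, gap: int = DEFAULT_GAP_BP) -> ClusterSet:
    """Single-linkage chaining of CpGs per chromosome at distance <= gap
    (boundary inclusive).  Input order is irrelevant; unannotated CpGs
    raise an error naming the offenders."""
    ids = pd.Index(sorted(set(cpgs)))
    pos = annotation.positions(ids)
    clusters: List[List[str]] = []
    singletons: List[str] = []
    for chrom, sub in pos.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")  # ids pre-sorted -> deterministic ties
        p = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(p) > gap) + 1
        for chunk in np.split(np.arange(len(p)), breaks):
            members = list(sub.index[chunk])
            if len(members) >= 2:
                clusters.append(members)
            else:
                singletons.extend(members)
    logger.info("clustering at gap=%d bp: %d clusters, %d singletons", gap, len(clusters), len(singletons))
    return ClusterSet(clusters=clusters, singletons=sorted(singletons), gap=gap)


def decluster(clusterset: ClusterSet, seed: int) -> List[str]:
    """One uniformly random member per cluster plus all singletons.

    Output size = n_clusters + n_singletons; deterministic for a given
    seed; no two returned CpGs lie within ``gap`` of one another.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    picks = [cluster[int(rng.integers(len(cluster)))] for cluster in clusterset.clusters]
    return sorted(picks + list(clusterset.singletons))


def _same_chrom_pairs(pos: pd.DataFrame, max_dist: int) -> pd.DataFrame:
    """All same-chromosome CpG pairs with |distance| <= max_dist."""
    rows = []
    for chrom, sub in pos.groupby("chrom", sort=True):
        sub = sub.sort_values("pos", kind="stable")
        p = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        hi = np.searchsorted(p, p + max_dist, side="right")
        for i in range(len(p)):
            for j in range(i + 1, hi[i]):
                rows.append((ids[i], ids[j], int(p[j] - p[i])))
    return pd.DataFrame(rows, columns=["cpg_a", "cpg_b", "dist"])


def correlation_decay_profile(
    datasets: Iterable[MethylationDataset],
    cpgs: Iterable[str],
    annotation: ProbeAnnotation,
    bin_bp: int = 100,
    max_dist: int = 8000,
    min_samples: int = MIN_SAMPLES_FOR_DECAY,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean pairwise Spearman correlation of Beta values by distance bin.

    Only datasets with at least ``min_samples`` samples contribute.  Every
    same-chromosome pair of ``cpgs`` at distance <= ``max_dist`` yields one
    Spearman rho per dataset (pairs with < 3 complete observations are
    skipped); pair-dataset values are averaged with equal weight within
    ``bin_bp``-wide distance bins.  With ``pooled=False`` (default) the
    per-pair values are first averaged across datasets, then binned; with
    ``pooled=True`` all pair-dataset values are pooled directly.

    Returns a DataFrame with ``bin_start``, ``bin_end``, ``mean_rho``,
    ``n_pairs`` rows.
    """
    use = [d for d in datasets if d.n_samples >= min_samples]
    if not use:
        raise InputError(f"no dataset with >= {min_samples} samples")
    ids = pd.Index(sorted(set(cpgs)))
    pairs = _same_chrom_pairs(annotation.positions(ids), max_dist)
    if pairs.empty:
        raise InputError("no same-chromosome CpG pairs within max_dist")

    rho_by_ds = []
    for ds in use:
        sub = ds.beta.reindex(ids)
        vals = sub.to_numpy(dtype=float)
        # rank-transform rows (average ranks; NaN stays NaN), then Pearson
        ranks = np.full_like(vals, np.nan)
        for r in range(vals.shape[0]):
            row = vals[r]
            ok = ~np.isnan(row)
            if ok.sum() >= 3:
                ranks[r, ok] = stats.rankdata(row[ok])
        idx_map = {c: k for k, c in enumerate(ids)}
        ia = pairs["cpg_a"].map(idx_map).to_numpy()
        ib = pairs["cpg_b"].map(idx_map).to_numpy()
        ra, rb = ranks[ia], ranks[ib]
        both = ~np.isnan(ra) & ~np.isnan(rb)
        n_ok = both.sum(axis=1)
        ra = np.where(both, ra, np.nan)
        rb = np.where(both, rb, np.nan)
        ca = ra - np.nanmean(ra, axis=1, keepdims=True)
        cb = rb - np.nanmean(rb, axis=1, keepdims=True)
        num = np.nansum(ca * cb, axis=1)
        den = np.sqrt(np.nansum(ca**2, axis=1) * np.nansum(cb**2, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = num / den
        rho[(n_ok < 3) | (den == 0)] = np.nan
        rho_by_ds.append(rho)

    rho_mat = np.vstack(rho_by_ds)  # datasets x pairs
    bins = (pairs["dist"].to_numpy() // bin_bp).astype(int)
    out_rows = []
    for b in np.unique(bins):
        sel = bins == b
        block = rho_mat[:, sel]
        if pooled:
            vals = block[~np.isnan(block)]
        else:
            vals = np.nanmean(block, axis=0)
            vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        out_rows.append(
            {
                "bin_start": int(b * bin_bp),
                "bin_end": int((b + 1) * bin_bp),
                "mean_rho": float(np.mean(vals)),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(out_rows)


def fit_exponential_decay(profile: pd.DataFrame, p0: Optional[tuple] = None) -> dict:
    """Fit mean_rho ~ a * exp(-d / length) to a binned decay profile.

    ``d`` is the bin midpoint; bins are weighted by pair count.  Returns
    ``{"amplitude": a, "length_bp": length}``.
    """
    d = (profile["bin_start"] + profile["bin_end"]).to_numpy() / 2.0
    y = profile["mean_rho"].to_numpy()
    w = np.sqrt(profile["n_pairs"].to_numpy(dtype=float))
    if p0 is None:
        p0 = (max(y.max(), 0.1), max(d.max() / 3.0, 1.0))
    popt, _ = optimize.curve_fit(
        lambda x, a, L: a * np.exp(-x / L), d, y, p0=p0, sigma=1.0 / np.maximum(w, 1e-9), maxfev=20_000
    )
    return {"amplitude": float(popt[0]), "length_bp": float(popt[1])}
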