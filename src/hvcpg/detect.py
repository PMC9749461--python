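"""Cross-dataset hypervariable-CpG (hvCpG) detection.

A CpG is called hypervariable when its methylation Beta variance falls in
the top ``i`` % of retained CpGs in at least ``j`` % of the datasets in
which it is covered, requiring coverage in at least ``min_datasets``
datasets (defaults i=5, j=65, min_datasets=15).  Because each dataset's
top-variance set is computed independently, independent datasets are not
expected to produce any call at these thresholds (per-CpG binomial tail
P(Bin(15, 0.05) >= 10) ~ 3e-10).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import InputError, MethylationDataset

logger = logging.getLogger(__name__)

DEFAULT_TOP_PCT = 5.0
DEFAULT_DATASET_FRACTION_PCT = 65.0
DEFAULT_MIN_DATASETS = 15


def dataset_variances(dataset: MethylationDataset) -> pd.Series:
    """Unbiased per-CpG sample variance of Beta values.

    Missing values are excluded per CpG; CpGs with fewer than 2 observed
    values get a missing variance (excluded from ranking downstream).
    """
    import warnings

    beta = dataset.beta.to_numpy(dtype=float)
    n_obs = (~np.isnan(beta)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # <2 obs handled below
        var = np.nanvar(beta, axis=1, ddof=1)
    var[n_obs < 2] = np.nan
    return pd.Series(var, index=dataset.beta.index, name=dataset.dataset_id)


def top_variance_flags(variances: pd.Series, top_pct: float = DEFAULT_TOP_PCT) -> pd.Series:
    """Flag CpGs in the top ``top_pct`` % of variance within this dataset.

    The cutoff is the k-th largest variance with k = floor(n * top_pct/100)
    over retained (non-missing) CpGs; ties at the cutoff are all included,
    which keeps the (i, j) threshold grid monotone.  CpGs with missing
    variance are dropped from the returned Series (not covered).
    """
    if not (0 < top_pct <= 100):
        raise InputError("top_pct must be in (0, 100]")
    v = variances.dropna()
    if v.empty:
        raise InputError("empty variance vector")
    n = len(v)
    k = int(math.floor(n * top_pct / 100.0))
    if k == 0:
        return pd.Series(False, index=v.index)
    arr = v.to_numpy()
    cutoff = np.partition(arr, n - k)[n - k]
    return pd.Series(arr >= cutoff, index=v.index)


def identify_hvcpgs(
    flags: Mapping[str, pd.Series],
    top_pct: float = DEFAULT_TOP_PCT,
    dataset_fraction_pct: float = DEFAULT_DATASET_FRACTION_PCT,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> pd.DataFrame:
    """Apply the cross-dataset intersection rule.

    ``flags`` maps dataset id to a boolean Series indexed by that dataset's
    retained CpGs (presence in the index = covered).  Returns a DataFrame
    indexed by every CpG covered anywhere, with columns ``n_covered``,
    ``n_hypervariable``, ``fraction``, ``in_background`` (covered in >=
    ``min_datasets`` datasets, the array background) and ``is_hvcpg``.
    """
    per_ds = pd.DataFrame({ds: s.astype(float) for ds, s in flags.items()})
    n_covered = per_ds.notna().sum(axis=1)
    n_hyper = per_ds.sum(axis=1, skipna=True).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = n_hyper / n_covered
    in_background = n_covered >= min_datasets
    is_hv = in_background & (fraction >= dataset_fraction_pct / 100.0)
    result = pd.DataFrame(
        {
            "n_covered": n_covered.astype(int),
            "n_hypervariable": n_hyper,
            "fraction": fraction,
            "in_background": in_background,
            "is_hvcpg": is_hv,
        }
    )
    result.index.name = "cpg"
    result.attrs["params"] = {
        "top_pct": top_pct,
        "dataset_fraction_pct": dataset_fraction_pct,
        "min_datasets": min_datasets,
    }
    logger.info(
        "hvCpG rule (%g%%, %g%%, >=%d): %d hvCpGs of %d background CpGs",
        top_pct, dataset_fraction_pct, min_datasets,
        int(is_hv.sum()), int(in_background.sum()),
    )
    return result


def detect_hvcpgs(
    datasets: Iterable[MethylationDataset],
    top_pct: float = DEFAULT_TOP_PCT,
    dataset_fraction_pct: float = DEFAULT_DATASET_FRACTION_PCT,
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> pd.DataFrame:
    """Convenience wrapper: variances -> per-dataset flags -> intersection."""
    flags = {}
    for ds in datasets:
        flags[ds.dataset_id] = top_variance_flags(dataset_variances(ds), top_pct)
    return identify_hvcpgs(flags, top_pct, dataset_fraction_pct, min_datasets)


def hvcpg_ids(result: pd.DataFrame) -> pd.Index:
    return result.index[result["is_hvcpg"]]


def array_background_ids(result: pd.DataFrame) -> pd.Index:
    return result.index[result["in_background"]]


def threshold_grid(
    variances: Mapping[str, pd.Series],
    i_values: Iterable[float] = tuple(range(1, 21)),
    j_values: Iterable[float] = tuple(range(50, 101, 5)),
    min_datasets: int = DEFAULT_MIN_DATASETS,
) -> pd.DataFrame:
    """hvCpG counts over the (variance-top-%, dataset-fraction-%) grid.

    Rows are variance thresholds ``i``, columns dataset fractions ``j``;
    counts are non-decreasing in ``i`` and non-increasing in ``j``.
    """
    i_values = list(i_values)
    j_values = list(j_values)
    counts = np.zeros((len(i_values), len(j_values)), dtype=int)
    for ii, i in enumerate(i_values):
        flags = {ds: top_variance_flags(v, i) for ds, v in variances.items()}
        per_ds = pd.DataFrame({ds: s.astype(float) for ds, s in flags.items()})
        n_covered = per_ds.notna().sum(axis=1)
        n_hyper = per_ds.sum(axis=1, skipna=True)
        covered_ok = n_covered >= min_datasets
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (n_hyper / n_covered).to_numpy()
        frac = frac[covered_ok.to_numpy()]
        for jj, j in enumerate(j_values):
            counts[ii, jj] = int((frac >= j / 100.0).sum())
    return pd.DataFrame(counts, index=pd.Index(i_values, name="variance_top_pct"),
                        columns=pd.Index(j_values, name="dataset_fraction_pct"))


def apply_reliability_filter(result: pd.DataFrame, unreliable: Iterable[str]) -> pd.DataFrame:
    """Remove technically unreliable probes from the hvCpG calls.

    Returns a copy of the result table with ``is_hvcpg`` switched off for
    ids in ``unreliable``; the removal count is logged.
    """
    unreliable = set(unreliable)
    out = result.copy()
    hit = out.index.isin(unreliable) & out["is_hvcpg"].to_numpy()
    out.loc[hit, "is_hvcpg"] = False
    logger.info("reliability filter removed %d hvCpGs", int(hit.sum()))
    out.attrs["n_unreliable_removed"] = int(hit.sum())
    return out
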