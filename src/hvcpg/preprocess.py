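"""Per-dataset probe filtering, M-value transform, covariate adjustment and
Tukey outer-fence outlier removal.

The processing order mirrors standard array QC practice: probe filters,
logit (M-value) transform, residual adjustment for the leading principal
components plus age/sex in a single linear model per CpG, back-transform to
Beta, then per-probe outlier masking at Tukey's outer fences
(Q1 - 3*IQR, Q3 + 3*IQR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import ConfigurationError, InputError, MethylationDataset

logger = logging.getLogger(__name__)

BETA_EPS = 1e-6  # clamp for Beta values at exactly 0 or 1 before the logit


@dataclass
class FilterRules:
    """Probe-exclusion rules applied per dataset.

    ``detection_p_threshold``/``detection_sample_fraction``: a probe is
    dropped when its detection p-value exceeds the threshold in more than
    the given fraction of samples (skipped when no detection p-values are
    present).  The three id lists hold multi-mapping, X/Y-chromosome and
    SNP-affected probes.  ``drop_any_missing`` removes probes with a missing
    Beta in any sample of the dataset.
    """

    detection_p_threshold: float = 0.01
    detection_sample_fraction: float = 0.05
    multimap_list: set = field(default_factory=set)
    xy_list: set = field(default_factory=set)
    snp_list: set = field(default_factory=set)
    drop_any_missing: bool = True

    def __post_init__(self) -> None:
        for v in (self.detection_p_threshold, self.detection_sample_fraction):
            if not (0 < v < 1):
                raise ConfigurationError("detection thresholds must be in (0, 1)")


@dataclass
class AdjustmentSpec:
    """Residual-adjustment model: first ``n_pcs`` principal components of the
    M-value matrix plus (optionally) age and sex, fitted per CpG in one
    linear model.  ``add_back_fitted_mean`` re-centres residuals on the
    fitted intercept so mean methylation is preserved through the
    back-transform."""

    n_pcs: int = 10
    use_age: bool = True
    use_sex: bool = True
    add_back_fitted_mean: bool = True
    back_transform: str = "base2"  # or "natural" (verbatim e^M/(1+e^M) mode)


def filter_probes(dataset: MethylationDataset, rules: FilterRules) -> MethylationDataset:
    """Drop probes failing any rule; samples are untouched.

    Idempotent: a filtered dataset passes through unchanged.  A per-rule
    removal count is logged and attached as ``.filter_report``.
    """
    beta = dataset.beta
    drop = pd.Series(False, index=beta.index)
    report = {}

    if dataset.detection_p is not None:
        frac_fail = (dataset.detection_p > rules.detection_p_threshold).mean(axis=1)
        rule = frac_fail > rules.detection_sample_fraction
        report["detection_p"] = int((rule & ~drop).sum())
        drop |= rule
    else:
        report["detection_p"] = 0

    for name, ids in (
        ("multimap", rules.multimap_list),
        ("xy", rules.xy_list),
        ("snp", rules.snp_list),
    ):
        rule = beta.index.isin(ids)
        report[name] = int((rule & ~drop.to_numpy()).sum())
        drop |= rule

    if rules.drop_any_missing:
        rule = beta.isna().any(axis=1)
        report["missing"] = int((rule & ~drop).sum())
        drop |= rule
    else:
        report["missing"] = 0

    keep = beta.index[~drop]
    logger.info("%s: probe filters removed %d/%d CpGs %s",
                dataset.dataset_id, int(drop.sum()), len(drop), report)
    out = dataset.subset_cpgs(keep)
    out.filter_report = report
    return out


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)); Beta values at 0/1 are clamped to
    [BETA_EPS, 1 - BETA_EPS] first."""
    b = np.asarray(beta, dtype=float)
    n_clamped = int(np.sum((b <= 0) | (b >= 1)))
    if n_clamped:
        logger.info("beta_to_m: clamped %d values at the Beta boundary", n_clamped)
    b = np.clip(b, BETA_EPS, 1 - BETA_EPS)
    out = np.log2(b / (1 - b))
    return out if out.shape else float(out)


def m_to_beta(m, mode: str = "base2"):
    """Inverse of the M transform.

    ``base2`` (default): 2^M / (1 + 2^M), the exact inverse of
    log2(beta/(1-beta)).  ``natural``: e^M / (1 + e^M), a legacy mode that
    does not round-trip with the base-2 logit.
    """
    from scipy.special import expit

    m = np.asarray(m, dtype=float)
    if mode == "base2":
        z = m * np.log(2.0)
    elif mode == "natural":
        z = m
    else:
        raise ConfigurationError(f"unknown back-transform mode: {mode!r}")
    out = expit(z)  # numerically stable logistic
    return out if out.shape else float(out)


def _pca_scores(m_centered: np.ndarray, n_pcs: int) -> np.ndarray:
    """Sample scores of the first n_pcs PCs of a CpG-centred M matrix
    (samples are the observations)."""
    # m_centered: CpG x sample, rows centred; SVD over the sample axis
    u, s, vt = np.linalg.svd(m_centered, full_matrices=False)
    return (vt[:n_pcs].T * s[:n_pcs])  # n_samples x n_pcs


def adjust_covariates(dataset: MethylationDataset, spec: AdjustmentSpec) -> MethylationDataset:
    """Residual-adjust every CpG for PCs of variation plus age/sex.

    Fits one ordinary-least-squares model per CpG of M on the sample scores
    of the first ``n_pcs`` PCs (computed from the CpG-centred M matrix),
    age (if available, non-constant and ``use_age``) and sex (likewise);
    the residuals, re-centred on the fitted intercept when
    ``add_back_fitted_mean``, are transformed back to Beta.

    Missing Beta values are mean-imputed for the fit and restored to
    missing in the output.
    """
    ns = dataset.n_samples
    if spec.n_pcs >= ns:
        raise ConfigurationError(f"n_pcs={spec.n_pcs} must be < n_samples={ns}")

    beta = dataset.beta.to_numpy(dtype=float)
    nan_mask = np.isnan(beta)
    m = beta_to_m(np.where(nan_mask, 0.5, beta))
    if nan_mask.any():
        row_mean = np.nanmean(np.where(nan_mask, np.nan, m), axis=1)
        m = np.where(nan_mask, row_mean[:, None], m)

    row_means = m.mean(axis=1)
    design_cols = [np.ones(ns)]
    if spec.n_pcs > 0:
        design_cols.append(_pca_scores(m - row_means[:, None], spec.n_pcs))

    cov = dataset.covariates
    for name, use in (("age", spec.use_age), ("sex", spec.use_sex)):
        if not use or name not in cov.columns:
            continue
        col = cov.loc[dataset.beta.columns, name]
        if col.isna().any():
            logger.warning("%s: covariate %s has missing values; dropped", dataset.dataset_id, name)
            continue
        x = (col == "male").astype(float).to_numpy() if name == "sex" else col.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("%s: covariate %s is constant; dropped", dataset.dataset_id, name)
            continue
        design_cols.append(x.reshape(ns, 1) if x.ndim == 1 else x)

    design = np.column_stack(design_cols)
    coef, *_ = np.linalg.lstsq(design, m.T, rcond=None)
    resid = m - (design @ coef).T
    if spec.add_back_fitted_mean:
        resid += coef[0][:, None]

    adj_beta = m_to_beta(resid, mode=spec.back_transform)
    adj_beta[nan_mask] = np.nan
    return MethylationDataset(
        dataset_id=dataset.dataset_id,
        beta=pd.DataFrame(adj_beta, index=dataset.beta.index, columns=dataset.beta.columns),
        covariates=dataset.covariates.copy(),
        detection_p=None,
        tissue=dataset.tissue,
        ethnicity=dataset.ethnicity,
    )


def tukey_outlier_mask(values, k: float = 3.0) -> np.ndarray:
    """Boolean mask of values outside Tukey's fences [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear-interpolation quantiles over non-missing values;
    missing values are never masked.  Requires >= 4 non-missing values.
    """
    v = np.asarray(values, dtype=float)
    finite = ~np.isnan(v)
    if finite.sum() == 0:
        raise InputError("all values missing")
    if finite.sum() < 4:
        raise InputError("need >= 4 non-missing values for Tukey fences")
    q1, q3 = np.quantile(v[finite], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros_like(v, dtype=bool)
    mask[finite] = (v[finite] < lo) | (v[finite] > hi)
    return mask


def remove_outliers(dataset: MethylationDataset, k: float = 3.0) -> MethylationDataset:
    """Set per-probe Beta outliers (Tukey outer fences, row-wise) to missing.

    Probes with fewer than 4 non-missing values are left untouched.
    """
    beta = dataset.beta.to_numpy(dtype=float).copy()
    finite = ~np.isnan(beta)
    enough = finite.sum(axis=1) >= 4
    rows = beta[enough]
    q1 = np.nanquantile(rows, 0.25, axis=1)
    q3 = np.nanquantile(rows, 0.75, axis=1)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        out = (rows < lo[:, None]) | (rows > hi[:, None])
    rows[out] = np.nan
    beta[enough] = rows
    n_masked = int(out.sum())
    if n_masked:
        logger.info("%s: masked %d outlier values", dataset.dataset_id, n_masked)
    return MethylationDataset(
        dataset_id=dataset.dataset_id,
        beta=pd.DataFrame(beta, index=dataset.beta.index, columns=dataset.beta.columns),
        covariates=dataset.covariates.copy(),
        detection_p=dataset.detection_p,
        tissue=dataset.tissue,
        ethnicity=dataset.ethnicity,
    )


def preprocess_dataset(
    dataset: MethylationDataset,
    rules: Optional[FilterRules] = None,
    spec: Optional[AdjustmentSpec] = None,
    tukey_k: float = 3.0,
) -> MethylationDataset:
    """Full per-dataset pipeline: filter -> adjust -> outlier removal."""
    rules = rules or FilterRules()
    spec = spec or AdjustmentSpec()
    out = filter_probes(dataset, rules)
    out = adjust_covariates(out, spec)
    return remove_outliers(out, k=tukey_k)
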