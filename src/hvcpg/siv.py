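"""Systemic interindividual variation (SIV): cross-germ-layer covariation
metrics and the multivariate-normal detection-power simulator.

SIV describes methylation that differs between individuals but is
concordant across tissues derived from different germ layers within each
individual, pointing to establishment before gastrulation.  The power
simulator asks how often a small multi-tissue screen (default four
individuals, three tissues) would re-detect a CpG whose cross-tissue mean
vector and covariance are given, by repeatedly sampling individuals from a
3-D multivariate normal and applying the SIV decision rule (per-individual
cross-tissue mean range >= 0.2, optionally plus an inter-tissue
correlation requirement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import FetalStudy, InputError

logger = logging.getLogger(__name__)

PSD_TOL = 1e-10


@dataclass(frozen=True)
class SIVPredicate:
    """Decision rule for calling SIV in a (individuals x 3 tissues) sample.

    ``range_threshold``: minimum range (max - min) of per-individual
    cross-tissue mean Beta values.  ``corr_threshold``: optional minimum
    inter-tissue Pearson correlation across individuals, applied to all
    three tissue pairs when ``require_all_pairs`` else to their mean.
    """

    range_threshold: float = 0.2
    corr_threshold: Optional[float] = None
    require_all_pairs: bool = True

    def __post_init__(self) -> None:
        if self.range_threshold < 0:
            raise InputError("range_threshold must be >= 0")


@dataclass
class PowerSimSpec:
    """Per-CpG inputs for the SIV power simulation.

    ``mu``: CpG x 3 tissue mean Beta matrix; ``sigma``: CpG x 3 x 3
    cross-tissue covariance (symmetrised, eigenvalues clipped to >= 0 when
    within ``PSD_TOL`` of zero).
    """

    mu: pd.DataFrame
    sigma: np.ndarray
    n_individuals: int = 4
    n_reps: int = 1000
    predicate: SIVPredicate = field(default_factory=SIVPredicate)
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        mu = self.mu.to_numpy(dtype=float)
        if mu.shape[1] != 3:
            raise InputError("mu must have three tissue columns")
        if np.nanmin(mu) < 0 or np.nanmax(mu) > 1:
            raise InputError("mu components must be Beta values in [0, 1]")
        sig = np.asarray(self.sigma, dtype=float)
        if sig.shape != (len(self.mu), 3, 3):
            raise InputError("sigma must be (n_cpgs, 3, 3)")


def inter_germlayer_correlation(study: FetalStudy, cpgs: Optional[Iterable[str]] = None) -> pd.Series:
    """Per-CpG mean inter-germ-layer Pearson r.

    Within each germ-layer-pair group, r is computed between the two
    tissues' Beta values across individuals; the per-CpG value is the
    unweighted average over groups with a defined r (groups with zero
    variance in either tissue are excluded; all-undefined CpGs get NaN).
    """
    idx = study.cpgs if cpgs is None else pd.Index(sorted(set(cpgs))).intersection(study.cpgs)
    per_group = []
    for name, (a, b) in study.groups.items():
        if a.shape[1] < 3:
            logger.warning("group %s has < 3 individuals; r undefined", name)
            per_group.append(pd.Series(np.nan, index=idx))
            continue
        av = a.reindex(idx).to_numpy(dtype=float)
        bv = b.reindex(idx).to_numpy(dtype=float)
        ac = av - av.mean(axis=1, keepdims=True)
        bc = bv - bv.mean(axis=1, keepdims=True)
        den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * bc).sum(axis=1) / den
        r[den == 0] = np.nan
        per_group.append(pd.Series(r, index=idx))
    out = pd.concat(per_group, axis=1).mean(axis=1, skipna=True)
    out.name = "mean_inter_germlayer_r"
    return out


def interindividual_variation(study: FetalStudy, cpgs: Optional[Iterable[str]] = None) -> pd.Series:
    """Range of per-individual cross-tissue mean Beta values.

    Each individual contributes the mean of its two tissue values; the
    per-CpG statistic is max - min of these means over all individuals in
    the study (27 in the reference design).  Symmetric in the tissue
    labels by construction.
    """
    idx = study.cpgs if cpgs is None else pd.Index(sorted(set(cpgs))).intersection(study.cpgs)
    means = []
    for a, b in study.groups.values():
        means.append((a.reindex(idx).to_numpy(dtype=float) + b.reindex(idx).to_numpy(dtype=float)) / 2.0)
    all_means = np.hstack(means)
    rng = np.nanmax(all_means, axis=1) - np.nanmin(all_means, axis=1)
    return pd.Series(rng, index=idx, name="interindividual_variation")


def siv_predicate(sample: np.ndarray, predicate: SIVPredicate) -> bool:
    """Evaluate the SIV rule on one (n_individuals x 3) Beta matrix."""
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2 or sample.shape[1] != 3 or sample.shape[0] < 2:
        raise InputError("sample must be (n_individuals >= 2) x 3")
    return bool(_siv_predicate_batch(sample[None, :, :], predicate)[0])


def _siv_predicate_batch(samples: np.ndarray, predicate: SIVPredicate) -> np.ndarray:
    """Vectorised predicate over (n_reps, n_individuals, 3) draws."""
    means = samples.mean(axis=2)  # reps x individuals
    rng = means.max(axis=1) - means.min(axis=1)
    ok = rng >= predicate.range_threshold
    if predicate.corr_threshold is not None:
        c = samples - samples.mean(axis=1, keepdims=True)
        pair_r = []
        for i, j in ((0, 1), (0, 2), (1, 2)):
            num = (c[:, :, i] * c[:, :, j]).sum(axis=1)
            den = np.sqrt((c[:, :, i] ** 2).sum(axis=1) * (c[:, :, j] ** 2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = num / den
            r[den == 0] = np.nan  # degenerate zero-variance tissue -> fails
            pair_r.append(r)
        pr = np.vstack(pair_r)  # 3 x reps
        if predicate.require_all_pairs:
            with np.errstate(invalid="ignore"):
                corr_ok = np.all(pr >= predicate.corr_threshold, axis=0)  # NaN fails
        else:
            all_nan = np.isnan(pr).all(axis=0)
            mean_r = np.full(pr.shape[1], -np.inf)
            if (~all_nan).any():
                mean_r[~all_nan] = np.nanmean(pr[:, ~all_nan], axis=0)
            corr_ok = mean_r >= predicate.corr_threshold
        ok &= corr_ok
    return ok


def _repair_psd(sigma: np.ndarray) -> np.ndarray:
    """Symmetrise and clip eigenvalues at 0 (tolerating -PSD_TOL)."""
    s = (sigma + sigma.swapaxes(-1, -2)) / 2.0
    w, v = np.linalg.eigh(s)
    if np.min(w) < -1e-6:
        raise InputError(f"covariance not PSD (min eigenvalue {np.min(w):.3g})")
    w = np.clip(w, 0.0, None)
    return np.einsum("...ij,...j,...kj->...ik", v, w, v)


def estimate_power_spec(
    tissue_values: dict,
    n_individuals: int = 4,
    n_reps: int = 1000,
    predicate: Optional[SIVPredicate] = None,
    seed: int = 0,
) -> PowerSimSpec:
    """Build a :class:`PowerSimSpec` from observed per-tissue Beta matrices.

    ``tissue_values`` maps three tissue names to CpG x sample DataFrames
    over shared CpGs and individuals; means and the unbiased cross-tissue
    covariance are estimated per CpG.
    """
    names = list(tissue_values)
    if len(names) != 3:
        raise InputError("exactly three tissues required")
    mats = [tissue_values[n].to_numpy(dtype=float) for n in names]
    idx = tissue_values[names[0]].index
    stacked = np.stack(mats, axis=2)  # cpg x individuals x 3
    mu = stacked.mean(axis=1)
    centred = stacked - mu[:, None, :]
    n = stacked.shape[1]
    sigma = np.einsum("cit,ciu->ctu", centred, centred) / (n - 1)
    return PowerSimSpec(
        mu=pd.DataFrame(np.clip(mu, 0, 1), index=idx, columns=names),
        sigma=sigma,
        n_individuals=n_individuals,
        n_reps=n_reps,
        predicate=predicate or SIVPredicate(),
        seed=seed,
    )


def siv_power(spec: PowerSimSpec) -> pd.DataFrame:
    """Monte-Carlo SIV detection power per CpG.

    For each CpG, draws ``n_reps`` cohorts of ``n_individuals`` independent
    3-vectors from MVN(mu, sigma) (clipped to [0, 1] unless ``clip`` is
    off) and reports the fraction meeting the SIV predicate plus its
    Monte-Carlo standard error sqrt(p(1-p)/n_reps).  Summary statistics
    (mean, median, IQR) live in ``result.attrs["summary"]``.
    """
    mu = spec.mu.to_numpy(dtype=float)
    sigma = _repair_psd(np.asarray(spec.sigma, dtype=float))
    chol = np.linalg.cholesky(sigma + PSD_TOL * np.eye(3))
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    powers = np.empty(len(mu))
    n_clipped = 0
    for c in range(len(mu)):
        z = rng.standard_normal((spec.n_reps, spec.n_individuals, 3))
        draws = mu[c] + z @ chol[c].T
        if spec.clip:
            n_clipped += int(((draws < 0) | (draws > 1)).sum())
            draws = np.clip(draws, 0.0, 1.0)
        powers[c] = _siv_predicate_batch(draws, spec.predicate).mean()
    if n_clipped:
        logger.info("siv_power: clipped %d out-of-range draws to [0, 1]", n_clipped)
    se = np.sqrt(powers * (1 - powers) / spec.n_reps)
    out = pd.DataFrame({"power": powers, "se": se}, index=spec.mu.index)
    q1, med, q3 = np.percentile(powers, [25, 50, 75]) if len(powers) else (np.nan,) * 3
    out.attrs["summary"] = {
        "mean": float(np.mean(powers)) if len(powers) else np.nan,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
    }
    return out
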