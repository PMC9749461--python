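"""Synthetic multi-dataset methylation studies with known ground truth.

The generator emulates the statistical structure of a collection of
Illumina-array cohorts: per-CpG logit-normal baselines with bimodal mean
methylation, a planted subset of CpGs whose Beta variance is high in every
dataset (intermediate-methylation mixtures), dataset-specific variable CpGs,
additively mQTL-driven CpGs (Hardy-Weinberg genotypes), low-rank batch
components, sex/age effects on small subsets, spatially clustered
co-methylated CpGs with correlation decaying exponentially with genomic
distance, and a fetal multi-tissue study with tunable inter-germ-layer
correlation.

All randomness flows from ``numpy.random.SeedSequence(config.seed)`` spawned
in a fixed order, so an identical configuration reproduces byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ConfigurationError, FetalStudy, MethylationDataset, ProbeAnnotation
from .preprocess import beta_to_m, m_to_beta

CATEGORIES = ("shared_hv", "dataset_specific_hv", "mqtl_driven", "cluster_member", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for :func:`simulate_study`.

    Counts of planted CpG categories must sum to at most ``n_cpgs``;
    categories are disjoint and every remaining CpG is labelled ``null``.
    """

    n_datasets: int = 30
    n_samples_per_dataset: int = 100
    n_cpgs: int = 20_000
    n_planted_shared_hv: int = 0
    n_planted_dataset_specific: int = 0
    n_planted_mqtl: int = 0
    n_planted_cluster: int = 0
    hv_variance_multiplier: float = 5.0
    mqtl_maf: float = 0.2
    mqtl_effect_m_scale: float = 1.0
    n_batch_components: int = 0
    cluster_gap_bp: int = 4000
    cluster_decay_bp: float = 2000.0
    interglayer_rho_planted: float = 0.7
    n_sex_effect: int = 0
    n_age_effect: int = 0
    sex_effect_m: float = 1.0
    age_effect_m_per_year: float = 0.02
    missing_rate: float = 0.0
    detection_fail_rate: float = 0.0
    unreliable_rate: float = 0.0
    seed: int = 0

    # Baselines are cohort-specific by default: each dataset draws its own
    # per-CpG mean, making within-dataset variance ranks independent across
    # datasets (the null model the cross-dataset intersection rule is
    # calibrated against).  Set True to give every dataset the same per-CpG
    # baseline mean instead.
    share_baseline_across_datasets: bool = False

    # noise geometry (M-value units); see docs/methods.md
    noise_logsd_mean: float = math.log(0.25)
    noise_logsd_sd: float = 0.35
    cluster_shared_sd: float = 0.7
    cluster_noise_sd: float = 0.3

    def validate(self) -> None:
        counts = (
            self.n_datasets,
            self.n_samples_per_dataset,
            self.n_cpgs,
            self.n_planted_shared_hv,
            self.n_planted_dataset_specific,
            self.n_planted_mqtl,
            self.n_planted_cluster,
            self.n_batch_components,
            self.n_sex_effect,
            self.n_age_effect,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        planted = (
            self.n_planted_shared_hv
            + self.n_planted_dataset_specific
            + self.n_planted_mqtl
            + self.n_planted_cluster
        )
        if planted > self.n_cpgs:
            raise ConfigurationError("planted category counts exceed n_cpgs")
        if not (0 < self.mqtl_maf <= 0.5):
            raise ConfigurationError("mqtl_maf must be in (0, 0.5]")
        if self.hv_variance_multiplier <= 0:
            raise ConfigurationError("hv_variance_multiplier must be positive")
        for frac in (self.missing_rate, self.detection_fail_rate, self.unreliable_rate):
            if not (0 <= frac <= 1):
                raise ConfigurationError("rates must be fractions in [0, 1]")
        if not (-1 <= self.interglayer_rho_planted <= 1):
            raise ConfigurationError("interglayer_rho_planted must be in [-1, 1]")


@dataclass
class GroundTruth:
    """Planted-signal labels for one simulated study.

    ``labels`` maps every CpG id to its single primary category;
    ``mqtl_effects`` holds one row per planted mQTL (cpg, snp, snp_chrom,
    snp_pos, beta_effect, maf); ``genotypes`` maps dataset id to the
    simulated dosage matrix (mQTL CpG x sample) for effect-recovery checks.
    """

    labels: pd.Series
    genotypes: dict = field(default_factory=dict)
    mqtl_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cpg", "snp", "cpg_chrom", "cpg_pos", "snp_chrom", "snp_pos", "beta_effect", "maf"]
        )
    )

    def cpgs_in(self, category: str) -> pd.Index:
        return self.labels.index[self.labels == category]


def _annotation(
    config: SimulationConfig, labels: pd.Series, runs: list, rng: np.random.Generator
) -> ProbeAnnotation:
    """Place CpGs on chr1..chr22.

    Non-cluster CpGs are spaced more than ``cluster_gap_bp`` apart so that
    planted clusters are the only sub-gap structure; within a cluster run
    consecutive gaps are ~0.1-1.2 kb, and runs start well beyond the decay
    range so cross-cluster (independent) pairs do not contaminate the
    co-methylation profile.
    """
    n = len(labels)
    cpgs = labels.index
    is_cluster = (labels == "cluster_member").to_numpy()
    gaps = np.empty(n)
    gaps[~is_cluster] = rng.uniform(config.cluster_gap_bp + 500, 30_000, (~is_cluster).sum())
    cl_idx = np.flatnonzero(is_cluster)
    gaps[cl_idx] = rng.uniform(100, 1200, len(cl_idx))
    starts = np.array([run[0] for run in runs], dtype=int)
    gaps[starts] = rng.uniform(max(config.cluster_gap_bp + 500, 9_000), 40_000, len(starts))
    # split into 22 chromosomes at cluster-safe boundaries; positions restart
    # per chromosome as the cumulative sum of that block's gaps
    run_id = np.full(n, -1)
    for k, run in enumerate(runs):
        run_id[run] = k
    chrom = np.empty(n, dtype=object)
    pos_all = np.empty(n, dtype=np.int64)
    bounds = np.linspace(0, n, 23).astype(int)
    for c in range(22):
        lo, hi = bounds[c], bounds[c + 1]
        # do not split a cluster run across chromosomes
        while hi < n and run_id[hi] != -1 and run_id[hi] == run_id[hi - 1]:
            hi += 1
        bounds[c + 1] = hi
        chrom[lo:hi] = f"chr{c + 1}"
        if lo < hi:
            pos_all[lo:hi] = np.cumsum(gaps[lo:hi]).astype(np.int64) + 1
    reliable = rng.random(n) >= config.unreliable_rate
    table = pd.DataFrame(
        {"chrom": chrom, "pos": pos_all, "reliable": reliable}, index=cpgs
    )
    return ProbeAnnotation(table)


def _cluster_runs(labels: pd.Series, rng: np.random.Generator) -> list:
    """Partition cluster_member CpGs (already contiguous) into runs of 3-8."""
    members = np.flatnonzero((labels == "cluster_member").to_numpy())
    runs, i = [], 0
    while i < len(members):
        size = int(rng.integers(3, 9))
        runs.append(members[i : i + size])
        i += size
    if len(runs) >= 2 and len(runs[-1]) < 2:  # avoid a trailing singleton run
        runs[-2] = np.concatenate([runs[-2], runs[-1]])
        runs.pop()
    return runs


def simulate_study(config: SimulationConfig):
    """Generate a multi-dataset methylation study with known ground truth.

    Returns ``(datasets, annotation, ground_truth)`` where ``datasets`` is a
    list of :class:`MethylationDataset` (disjoint cohorts), Beta values lie
    in [0, 1], and every CpG carries exactly one category label.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (ss_layout, ss_annot, ss_fx, *ss_datasets) = ss.spawn(3 + config.n_datasets)
    rng = np.random.default_rng(ss_layout)

    n = config.n_cpgs
    cpgs = pd.Index([f"cg{i:08d}" for i in range(n)], name="cpg")

    # category layout: cluster members are contiguous blocks; other planted
    # categories are scattered among the remaining slots
    labels = np.array(["null"] * n, dtype=object)
    k_cl = config.n_planted_cluster
    cl_start = rng.integers(0, n - k_cl + 1) if k_cl else 0
    labels[cl_start : cl_start + k_cl] = "cluster_member"
    free = np.flatnonzero(labels == "null")
    picks = rng.choice(
        free,
        size=config.n_planted_shared_hv + config.n_planted_dataset_specific + config.n_planted_mqtl,
        replace=False,
    )
    a = config.n_planted_shared_hv
    b = a + config.n_planted_dataset_specific
    labels[picks[:a]] = "shared_hv"
    labels[picks[a:b]] = "dataset_specific_hv"
    labels[picks[b:]] = "mqtl_driven"
    labels = pd.Series(labels, index=cpgs, name="category")

    runs = _cluster_runs(labels, rng)
    annotation = _annotation(config, labels, runs, np.random.default_rng(ss_annot))

    # global per-CpG characteristics (planted-signal geometry)
    fx = np.random.default_rng(ss_fx)

    def _baseline_mu_m(gen: np.random.Generator) -> np.ndarray:
        """Per-CpG baseline means: bimodal Beta mixture, logit-transformed."""
        mix = gen.random(n)
        mu_beta = np.where(
            mix < 0.35,
            gen.normal(0.10, 0.04, n),
            np.where(mix < 0.70, gen.normal(0.90, 0.04, n), gen.uniform(0.15, 0.85, n)),
        )
        return beta_to_m(np.clip(mu_beta, 0.02, 0.98))

    mu_m_shared = _baseline_mu_m(fx)

    # hypervariable CpGs: 2-3 component mixtures at intermediate Beta; half-
    # separation scales with sqrt(multiplier) so Beta variance ~ multiplier
    hv_mask = labels.isin(["shared_hv", "dataset_specific_hv"]).to_numpy()
    n_hv = int(hv_mask.sum())
    hv_center = fx.uniform(0.35, 0.65, n_hv)
    hv_delta = np.minimum(0.12 * math.sqrt(config.hv_variance_multiplier), 0.28)
    hv_ncomp = fx.integers(2, 4, n_hv)
    hv_p = fx.uniform(0.3, 0.7, n_hv)
    ds_assign = fx.integers(0, config.n_datasets, n)  # dataset owning each ds-specific CpG

    mqtl_mask = (labels == "mqtl_driven").to_numpy()
    n_mqtl = int(mqtl_mask.sum())
    mqtl_rows = []
    mqtl_cpg_pos = annotation.table.loc[labels.index[mqtl_mask]]
    for i, (cpg, row) in enumerate(mqtl_cpg_pos.iterrows()):
        cis = fx.random() < 0.9
        offset = int(fx.integers(1_000, 500_000)) if cis else int(fx.integers(2_000_000, 10_000_000))
        mqtl_rows.append(
            {
                "cpg": cpg,
                "snp": f"rs{i:07d}",
                "cpg_chrom": row["chrom"],
                "cpg_pos": int(row["pos"]),
                "snp_chrom": row["chrom"],
                "snp_pos": int(row["pos"]) + offset,
                "beta_effect": config.mqtl_effect_m_scale,
                "maf": config.mqtl_maf,
            }
        )
    truth = GroundTruth(labels=labels, mqtl_effects=pd.DataFrame(mqtl_rows))

    hv_idx_all = np.flatnonzero(hv_mask)
    cluster_covs = []
    for run in runs:
        pos = annotation.table["pos"].to_numpy()[run].astype(float)
        d = np.abs(pos[:, None] - pos[None, :])
        cov = np.exp(-d / config.cluster_decay_bp)
        cluster_covs.append(np.linalg.cholesky(cov + 1e-10 * np.eye(len(run))))

    datasets = []
    for d_idx, ss_d in enumerate(ss_datasets):
        drng = np.random.default_rng(ss_d)
        ns = config.n_samples_per_dataset
        mu_m = mu_m_shared if config.share_baseline_across_datasets else _baseline_mu_m(drng)
        sd = np.exp(drng.normal(config.noise_logsd_mean, config.noise_logsd_sd, n))
        m = mu_m[:, None] + sd[:, None] * drng.standard_normal((n, ns))

        # hypervariable mixtures (active everywhere for shared, in one dataset
        # for dataset-specific); component membership is cohort-specific
        active = hv_mask & (
            (labels == "shared_hv").to_numpy()
            | ((labels == "dataset_specific_hv").to_numpy() & (ds_assign == d_idx))
        )
        act = np.flatnonzero(active)
        if len(act):
            loc = np.searchsorted(hv_idx_all, act)
            comp = drng.random((len(act), ns))
            centers_lo = np.clip(hv_center[loc] - hv_delta, 0.2, 0.8)
            centers_hi = np.clip(hv_center[loc] + hv_delta, 0.2, 0.8)
            centers_mid = hv_center[loc]
            c_beta = np.where(
                comp < hv_p[loc, None],
                centers_lo[:, None],
                np.where(
                    (hv_ncomp[loc, None] == 3) & (comp < (hv_p[loc, None] + 1) / 2),
                    centers_mid[:, None],
                    centers_hi[:, None],
                ),
            )
            m[act] = beta_to_m(c_beta) + 0.2 * drng.standard_normal((len(act), ns))

        # mQTL CpGs: additive genotype effect on the M scale, HWE genotypes
        if n_mqtl:
            g = drng.binomial(2, config.mqtl_maf, (n_mqtl, ns)).astype(float)
            m[mqtl_mask] += config.mqtl_effect_m_scale * g
            truth.genotypes[f"dataset_{d_idx:02d}"] = pd.DataFrame(
                g, index=cpgs[mqtl_mask], columns=[f"d{d_idx}_s{j}" for j in range(ns)]
            )

        # clustered co-methylation: correlated deviations, corr = exp(-d/decay)
        for run, chol in zip(runs, cluster_covs):
            z = chol @ drng.standard_normal((len(run), ns))
            m[run] = (
                mu_m[run, None]
                + config.cluster_shared_sd * z
                + config.cluster_noise_sd * drng.standard_normal((len(run), ns))
            )

        # low-rank batch structure
        if config.n_batch_components:
            scores = drng.standard_normal((config.n_batch_components, ns))
            loadings = drng.normal(0, 0.3, (n, config.n_batch_components))
            m += loadings @ scores

        # covariates and their planted effects on null CpGs
        sex = np.where(np.arange(ns) % 2 == 0, "male", "female")
        sex = drng.permutation(sex)
        age = drng.uniform(20, 70, ns)
        null_idx = np.flatnonzero((labels == "null").to_numpy())
        if config.n_sex_effect:
            sx = null_idx[: config.n_sex_effect]
            m[sx] += config.sex_effect_m * (sex == "male")[None, :]
        if config.n_age_effect:
            ag = null_idx[config.n_sex_effect : config.n_sex_effect + config.n_age_effect]
            m[ag] += config.age_effect_m_per_year * (age - 45.0)[None, :]

        beta = m_to_beta(m)
        if config.missing_rate:
            beta[drng.random(beta.shape) < config.missing_rate] = np.nan

        detection_p = None
        if config.detection_fail_rate:
            dp = drng.uniform(0, 0.01, beta.shape)
            bad = drng.random(n) < config.detection_fail_rate
            fail = drng.random(beta.shape) < 0.10  # >5% of samples in expectation
            dp[bad[:, None] & fail] = drng.uniform(0.02, 0.5, int((bad[:, None] & fail).sum()))
            detection_p = pd.DataFrame(dp, index=cpgs, columns=[f"d{d_idx}_s{j}" for j in range(ns)])

        samples = [f"d{d_idx}_s{j}" for j in range(ns)]
        datasets.append(
            MethylationDataset(
                dataset_id=f"dataset_{d_idx:02d}",
                beta=pd.DataFrame(beta, index=cpgs, columns=samples),
                covariates=pd.DataFrame({"age": age, "sex": sex}, index=samples),
                detection_p=detection_p,
                tissue=f"tissue_{d_idx % 5}",
                ethnicity=f"eth_{d_idx % 4}",
            )
        )
    return datasets, annotation, truth


def simulate_fetal_multitissue(
    n_individuals_per_pair: Union[int, Sequence[int]],
    n_cpgs: int,
    rho_planted: float,
    seed: int,
    n_siv_cpgs: Optional[int] = None,
    noise_sd: float = 0.08,
) -> tuple:
    """Simulate a fetal two-tissue study across three germ-layer pairs.

    Planted CpGs (the first ``n_siv_cpgs``, default all) share a
    per-individual latent methylation level across both tissues with
    correlation ``rho_planted``; remaining CpGs are independent across
    tissues.  Group sizes may be a single count or a triple matching the
    (endo-meso, endo-ecto, meso-ecto) design.

    Returns ``(FetalStudy, labels)`` with labels ``siv_planted``/``null``.
    """
    if not (-1 <= rho_planted <= 1):
        raise ConfigurationError("rho_planted must be in [-1, 1]")
    if isinstance(n_individuals_per_pair, int):
        sizes = (n_individuals_per_pair,) * 3
    else:
        sizes = tuple(n_individuals_per_pair)
        if len(sizes) != 3:
            raise ConfigurationError("n_individuals_per_pair must be an int or a triple")
    if min(sizes) < 2:
        raise ConfigurationError("each germ-layer pair needs >= 2 individuals")
    n_siv = n_cpgs if n_siv_cpgs is None else int(n_siv_cpgs)
    if n_siv > n_cpgs:
        raise ConfigurationError("n_siv_cpgs exceeds n_cpgs")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cpgs = pd.Index([f"cg{i:08d}" for i in range(n_cpgs)], name="cpg")
    mu = rng.uniform(0.25, 0.75, n_cpgs)
    rho = float(rho_planted)
    # Cholesky of [[1, rho], [rho, 1]]
    c21, c22 = rho, math.sqrt(max(0.0, 1.0 - rho * rho))

    groups = {}
    ind_offset = 0
    for label, k in zip(FetalStudy.GROUP_LABELS, sizes):
        za = rng.standard_normal((n_cpgs, k))
        zb = rng.standard_normal((n_cpgs, k))
        dev_a = za
        dev_b = zb.copy()
        dev_b[:n_siv] = c21 * za[:n_siv] + c22 * zb[:n_siv]
        a = np.clip(mu[:, None] + noise_sd * dev_a, 0.005, 0.995)
        b = np.clip(mu[:, None] + noise_sd * dev_b, 0.005, 0.995)
        inds = [f"ind{ind_offset + j:03d}" for j in range(k)]
        ind_offset += k
        groups[label] = (
            pd.DataFrame(a, index=cpgs, columns=inds),
            pd.DataFrame(b, index=cpgs, columns=inds),
        )
    labels = pd.Series(
        np.where(np.arange(n_cpgs) < n_siv, "siv_planted", "null"), index=cpgs, name="category"
    )
    return FetalStudy(groups), labels


def simulate_mqtl_table(ground_truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Emit the mQTL summary table for the planted mQTLs.

    One row per planted SNP-CpG association with columns
    ``cpg, snp, beta, maf, kind, p``; ``kind`` is ``cis`` when the SNP lies
    within 1 Mb of its CpG, else ``trans``.
    """
    eff = ground_truth.mqtl_effects
    if eff.empty:
        return pd.DataFrame(columns=["cpg", "snp", "beta", "maf", "kind", "p"])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 104729)))
    same_chrom = eff["snp_chrom"].to_numpy() == eff["cpg_chrom"].to_numpy()
    dist = np.abs(eff["snp_pos"].to_numpy() - eff["cpg_pos"].to_numpy())
    kind = np.where(same_chrom & (dist <= 1_000_000), "cis", "trans")
    return pd.DataFrame(
        {
            "cpg": eff["cpg"],
            "snp": eff["snp"],
            "beta": eff["beta_effect"],
            "maf": eff["maf"],
            "kind": kind,
            "p": rng.uniform(1e-30, 1e-15, len(eff)),
        }
    )


def simulate_annotation_tracks(
    annotation: ProbeAnnotation,
    ground_truth: GroundTruth,
    n_intervals: int,
    enriched_category: str,
    fold: float,
    seed: int,
    window_bp: int = 10_000,
    interval_len_bp: int = 500,
    set_background_rate: float = 0.05,
):
    """Place feature intervals enriched near CpGs of one planted category.

    Interval anchors are sampled with weight ``fold`` at CpGs of
    ``enriched_category`` and weight 1 elsewhere, so category CpGs fall
    within ``window_bp`` of an interval at ``fold`` times the background
    rate in expectation.  Also draws a published-CpG-like id set with the
    same fold enrichment.

    Returns ``(intervals, cpg_set)``: a BED-style DataFrame
    (chrom, start, end, name; 0-based half-open) and a set of CpG ids.
    """
    if fold < 1:
        raise ConfigurationError("fold must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tab = annotation.table
    in_cat = ground_truth.labels.reindex(tab.index).eq(enriched_category).to_numpy()
    weights = np.where(in_cat, fold, 1.0)
    weights = weights / weights.sum()
    rows = []
    if n_intervals:
        anchors = rng.choice(len(tab), size=n_intervals, replace=True, p=weights)
        for j, ai in enumerate(anchors):
            pos0 = int(tab["pos"].iloc[ai]) - 1  # 0-based
            offset = int(rng.integers(-(window_bp - interval_len_bp), window_bp - interval_len_bp))
            start = max(0, pos0 + offset)
            rows.append(
                {
                    "chrom": tab["chrom"].iloc[ai],
                    "start": start,
                    "end": start + interval_len_bp,
                    "name": f"feat{j:05d}",
                }
            )
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    p_in = min(1.0, fold * set_background_rate)
    take = np.where(in_cat, rng.random(len(tab)) < p_in, rng.random(len(tab)) < set_background_rate)
    cpg_set = set(tab.index[take])
    return intervals, cpg_set
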