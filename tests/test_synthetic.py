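"""Generator contracts: determinism, planted-signal recovery, ground-truth
labelling, and the fetal multi-tissue and annotation-track simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hvcpg as h


def test_invalid_configs_rejected():
    with pytest.raises(h.ConfigurationError):
        h.SimulationConfig(n_cpgs=10, n_planted_shared_hv=20).validate()
    with pytest.raises(h.ConfigurationError):
        h.SimulationConfig(mqtl_maf=0.7).validate()
    with pytest.raises(h.ConfigurationError):
        h.SimulationConfig(n_planted_mqtl=-1).validate()
    with pytest.raises(h.ConfigurationError):
        h.simulate_fetal_multitissue(5, 100, rho_planted=1.5, seed=0)


def test_no_planting_gives_all_null_labels():
    cfg = h.SimulationConfig(n_datasets=2, n_samples_per_dataset=30, n_cpgs=300,
                             hv_variance_multiplier=1.0, seed=0)
    _, _, truth = h.simulate_study(cfg)
    assert (truth.labels == "null").all()


def test_every_cpg_has_exactly_one_category(small_study):
    cfg, _, _, truth = small_study
    counts = truth.labels.value_counts()
    assert counts.get("shared_hv", 0) == cfg.n_planted_shared_hv
    assert counts.get("dataset_specific_hv", 0) == cfg.n_planted_dataset_specific
    assert counts.get("mqtl_driven", 0) == cfg.n_planted_mqtl
    assert counts.get("cluster_member", 0) == cfg.n_planted_cluster
    assert counts.sum() == cfg.n_cpgs


def test_seed_determinism_bitwise():
    cfg = h.SimulationConfig(n_datasets=2, n_samples_per_dataset=25, n_cpgs=200,
                             n_planted_shared_hv=10, n_planted_cluster=12,
                             n_planted_mqtl=5, missing_rate=0.01,
                             detection_fail_rate=0.05, seed=1)
    a_ds, a_ann, a_truth = h.simulate_study(cfg)
    b_ds, b_ann, b_truth = h.simulate_study(cfg)
    for a, b in zip(a_ds, b_ds):
        assert a.beta.equals(b.beta)
        assert a.covariates.equals(b.covariates)
        assert (a.detection_p is None) == (b.detection_p is None)
        if a.detection_p is not None:
            assert a.detection_p.equals(b.detection_p)
    assert a_ann.table.equals(b_ann.table)
    assert a_truth.labels.equals(b_truth.labels)


def test_beta_values_in_unit_interval(small_study):
    _, datasets, _, _ = small_study
    for ds in datasets:
        v = ds.beta.to_numpy()
        assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1


def test_shared_hv_variance_exceeds_null_everywhere(small_study):
    _, datasets, _, truth = small_study
    shared = truth.cpgs_in("shared_hv")
    null = truth.cpgs_in("null")
    for ds in datasets:
        var = h.dataset_variances(ds)
        # planted shared CpGs sit above the null 95th percentile in every cohort
        assert var[shared].min() > var[null].quantile(0.95)


def test_dataset_specific_hv_in_exactly_one_dataset():
    cfg = h.SimulationConfig(n_datasets=6, n_samples_per_dataset=80, n_cpgs=2000,
                             n_planted_dataset_specific=20, seed=9)
    datasets, _, truth = h.simulate_study(cfg)
    specific = truth.cpgs_in("dataset_specific_hv")
    null = truth.cpgs_in("null")
    exceeds = pd.DataFrame(
        {
            ds.dataset_id: h.dataset_variances(ds)[specific] > h.dataset_variances(ds)[null].max()
            for ds in datasets
        }
    )
    assert (exceeds.sum(axis=1) == 1).all()


def test_mqtl_zero_effect_slope_within_3se():
    """With a zero planted effect the genotype-methylation slope is null."""
    cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=300, n_cpgs=400,
                             n_planted_mqtl=30, mqtl_effect_m_scale=0.0, seed=5)
    (ds,), _, truth = h.simulate_study(cfg)
    g = truth.genotypes[ds.dataset_id]
    m = pd.DataFrame(h.beta_to_m(ds.beta.to_numpy()), index=ds.beta.index, columns=ds.beta.columns)
    n_out = 0
    for cpg in g.index:
        fit = stats.linregress(g.loc[cpg], m.loc[cpg])
        n_out += abs(fit.slope) >= 3 * fit.stderr
    assert n_out <= 2  # ~0.3% two-sided tail over 30 CpGs


def test_mqtl_planted_effect_recovered_within_3se():
    cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=250, n_cpgs=300,
                             n_planted_mqtl=25, mqtl_effect_m_scale=0.8, mqtl_maf=0.3, seed=6)
    (ds,), _, truth = h.simulate_study(cfg)
    g = truth.genotypes[ds.dataset_id]
    m = pd.DataFrame(h.beta_to_m(ds.beta.to_numpy()), index=ds.beta.index, columns=ds.beta.columns)
    n_out = 0
    for cpg in g.index:
        fit = stats.linregress(g.loc[cpg], m.loc[cpg])
        n_out += abs(fit.slope - 0.8) >= 3 * fit.stderr
    assert n_out <= 2


class TestFetalSimulator:
    def test_reference_design_gives_27_individuals(self):
        study, _ = h.simulate_fetal_multitissue((9, 10, 8), n_cpgs=50, rho_planted=0.7, seed=0)
        assert study.n_individuals == 27
        assert [a.shape[1] for a, _ in study.groups.values()] == [9, 10, 8]

    def test_rho_one_gives_perfect_correlation(self):
        study, labels = h.simulate_fetal_multitissue(6, n_cpgs=100, rho_planted=1.0, seed=2)
        r = h.inter_germlayer_correlation(study, labels.index[labels == "siv_planted"])
        assert np.allclose(r.dropna(), 1.0)

    def test_rho_zero_null_mean_near_zero(self):
        study, _ = h.simulate_fetal_multitissue((9, 10, 8), n_cpgs=1500, rho_planted=0.0, seed=3)
        r = h.inter_germlayer_correlation(study)
        assert abs(r.mean()) < 0.1


class TestMqtlTable:
    def test_zero_planted_gives_empty_table(self):
        cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=20, n_cpgs=100, seed=0)
        _, _, truth = h.simulate_study(cfg)
        assert h.simulate_mqtl_table(truth, cfg).empty

    def test_variance_explained_matches_formula(self):
        cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=20, n_cpgs=200,
                                 n_planted_mqtl=15, mqtl_effect_m_scale=0.5, mqtl_maf=0.25, seed=4)
        _, _, truth = h.simulate_study(cfg)
        table = h.simulate_mqtl_table(truth, cfg)
        summ = h.mqtl_summary(table)
        expected = 2 * 0.5**2 * 0.25 * 0.75
        assert np.allclose(summ["mean_var_explained"], expected)
        assert set(table["kind"]) <= {"cis", "trans"}

    def test_roundtrip_through_tsv(self, tmp_path):
        cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=20, n_cpgs=200,
                                 n_planted_mqtl=15, seed=4)
        _, _, truth = h.simulate_study(cfg)
        table = h.simulate_mqtl_table(truth, cfg)
        from hvcpg import io as hio
        path = tmp_path / "mqtl.tsv"
        hio.write_mqtl_table(table, path)
        back = hio.read_mqtl_table(path)
        pd.testing.assert_frame_equal(back, table.reset_index(drop=True), check_exact=False)


class TestAnnotationTracks:
    def _study(self, seed=0):
        cfg = h.SimulationConfig(n_datasets=1, n_samples_per_dataset=20, n_cpgs=3000,
                                 n_planted_shared_hv=300, seed=seed)
        _, annotation, truth = h.simulate_study(cfg)
        return annotation, truth

    def test_fold_below_one_rejected(self):
        annotation, truth = self._study()
        with pytest.raises(h.ConfigurationError):
            h.simulate_annotation_tracks(annotation, truth, 10, "shared_hv", fold=0.5, seed=0)

    def test_zero_intervals_gives_zero_proximity(self):
        annotation, truth = self._study()
        intervals, _ = h.simulate_annotation_tracks(annotation, truth, 0, "shared_hv", fold=2.0, seed=0)
        assert intervals.empty

    def test_strong_fold_detected_as_enrichment(self):
        annotation, truth = self._study(seed=1)
        intervals, _ = h.simulate_annotation_tracks(annotation, truth, 400, "shared_hv", fold=5.0, seed=1)
        target = list(truth.cpgs_in("shared_hv"))
        comparator = list(truth.cpgs_in("null"))
        prox = h.proximity_enrichment(target, comparator, annotation, intervals, distances=(10_000,))
        assert prox["odds_ratio"].iloc[0] > 1
        assert prox["p"].iloc[0] < 0.05

    def test_fold_one_is_null(self):
        """At fold 1 the interval placement carries no category signal."""
        n_sig = 0
        for seed in range(10):
            annotation, truth = self._study(seed=seed)
            intervals, _ = h.simulate_annotation_tracks(annotation, truth, 200, "shared_hv", fold=1.0, seed=seed)
            prox = h.proximity_enrichment(
                list(truth.cpgs_in("shared_hv")), list(truth.cpgs_in("null")),
                annotation, intervals, distances=(10_000,),
            )
            n_sig += prox["p"].iloc[0] < 0.05
        assert n_sig <= 2
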