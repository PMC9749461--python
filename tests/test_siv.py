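"""Cross-germ-layer covariation metrics and the MVN SIV power simulator."""

import numpy as np
import pandas as pd
import pytest

import hvcpg as h


def fetal_from_arrays(a_by_group, b_by_group, cpgs=None):
    groups = {}
    for label, a, b in zip(h.FetalStudy.GROUP_LABELS, a_by_group, b_by_group):
        idx = cpgs or [f"cg{i}" for i in range(a.shape[0])]
        cols = [f"i{j}" for j in range(a.shape[1])]
        groups[label] = (pd.DataFrame(a, index=idx, columns=cols),
                         pd.DataFrame(b, index=idx, columns=cols))
    return h.FetalStudy(groups)


class TestInterGermlayerCorrelation:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        mats = [rng.uniform(0.2, 0.8, (5, 4)) for _ in range(3)]
        study = fetal_from_arrays(mats, mats)
        assert np.allclose(h.inter_germlayer_correlation(study), 1.0)

    def test_negated_gives_minus_one(self):
        rng = np.random.default_rng(1)
        mats = [rng.uniform(0.2, 0.8, (5, 4)) for _ in range(3)]
        study = fetal_from_arrays(mats, [1.0 - m for m in mats])
        assert np.allclose(h.inter_germlayer_correlation(study), -1.0)

    def test_affine_rescaling_invariant(self):
        rng = np.random.default_rng(2)
        a = [rng.uniform(0.3, 0.7, (8, 6)) for _ in range(3)]
        b = [rng.uniform(0.3, 0.7, (8, 6)) for _ in range(3)]
        base = h.inter_germlayer_correlation(fetal_from_arrays(a, b))
        scaled = h.inter_germlayer_correlation(
            fetal_from_arrays([0.5 * m + 0.1 for m in a], [0.5 * m + 0.1 for m in b]))
        assert np.allclose(base, scaled)

    def test_planted_rho_recovered(self):
        study, _ = h.simulate_fetal_multitissue((9, 10, 8), n_cpgs=2000, rho_planted=0.7, seed=4)
        r = h.inter_germlayer_correlation(study)
        assert abs(r.mean() - 0.7) < 0.05

    def test_zero_variance_group_excluded(self):
        rng = np.random.default_rng(3)
        a = [rng.uniform(0.2, 0.8, (2, 5)) for _ in range(3)]
        b = [m.copy() for m in a]
        a[0][0, :] = 0.5  # flat tissue-A vector in group 1, CpG 0
        r = h.inter_germlayer_correlation(fetal_from_arrays(a, b))
        assert r.iloc[0] == pytest.approx(1.0)  # remaining two groups still perfect


class TestInterindividualVariation:
    def test_identical_individuals_zero(self):
        a = [np.full((3, 4), 0.4)] * 3
        study = fetal_from_arrays(a, a)
        assert np.allclose(h.interindividual_variation(study), 0.0)

    def test_range_of_means(self):
        # one CpG; per-individual cross-tissue means 0.2, 0.5, 0.7 in group 1
        a = [np.array([[0.1, 0.4, 0.6]]), np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])]
        b = [np.array([[0.3, 0.6, 0.8]]), np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]])]
        study = fetal_from_arrays(a, b)
        assert h.interindividual_variation(study).iloc[0] == pytest.approx(0.5)

    def test_tissue_label_symmetry(self):
        rng = np.random.default_rng(5)
        a = [rng.uniform(0, 1, (6, 5)) for _ in range(3)]
        b = [rng.uniform(0, 1, (6, 5)) for _ in range(3)]
        v1 = h.interindividual_variation(fetal_from_arrays(a, b))
        v2 = h.interindividual_variation(fetal_from_arrays(b, a))
        assert np.allclose(v1, v2)


class TestSivPredicate:
    def test_vacuous_predicate_true(self):
        sample = np.full((4, 3), 0.5)
        assert h.siv_predicate(sample, h.SIVPredicate(range_threshold=0.0))

    def test_identical_individuals_false(self):
        sample = np.full((4, 3), 0.5)
        assert not h.siv_predicate(sample, h.SIVPredicate(range_threshold=0.2))

    def test_hand_computed_example(self):
        sample = np.array([
            [0.10, 0.20, 0.30],   # mean 0.20
            [0.40, 0.50, 0.60],   # mean 0.50
            [0.20, 0.25, 0.30],   # mean 0.25
            [0.15, 0.20, 0.25],   # mean 0.20
        ])
        # brute-force: range of means, then all pairwise tissue correlations
        means = sample.mean(axis=1)
        rng_means = means.max() - means.min()
        assert rng_means == pytest.approx(0.30)
        assert h.siv_predicate(sample, h.SIVPredicate(range_threshold=0.2))
        assert not h.siv_predicate(sample, h.SIVPredicate(range_threshold=0.35))
        cors = [np.corrcoef(sample[:, i], sample[:, j])[0, 1]
                for i, j in ((0, 1), (0, 2), (1, 2))]
        pred = h.SIVPredicate(range_threshold=0.2, corr_threshold=min(cors) - 1e-9)
        assert h.siv_predicate(sample, pred)
        pred_hi = h.SIVPredicate(range_threshold=0.2, corr_threshold=min(cors) + 1e-6)
        assert not h.siv_predicate(sample, pred_hi)

    def test_degenerate_tissue_fails_with_corr(self):
        sample = np.array([[0.1, 0.5, 0.5], [0.5, 0.5, 0.5], [0.9, 0.5, 0.5], [0.3, 0.5, 0.5]])
        pred = h.SIVPredicate(range_threshold=0.0, corr_threshold=0.5)
        assert not h.siv_predicate(sample, pred)


def _spec(mu_val, sd, n_cpgs=3, rho=0.0, **kw):
    idx = [f"cg{i}" for i in range(n_cpgs)]
    mu = pd.DataFrame(np.full((n_cpgs, 3), mu_val), index=idx)
    cov = sd**2 * ((1 - rho) * np.eye(3) + rho * np.ones((3, 3)))
    sigma = np.tile(cov, (n_cpgs, 1, 1))
    return h.PowerSimSpec(mu=mu, sigma=sigma, **kw)


class TestSivPower:
    def test_zero_threshold_power_exactly_one(self):
        spec = _spec(0.5, 0.05, predicate=h.SIVPredicate(range_threshold=0.0), seed=1)
        assert (h.siv_power(spec)["power"] == 1.0).all()

    def test_point_mass_power_exactly_zero(self):
        spec = _spec(0.5, 0.0, predicate=h.SIVPredicate(range_threshold=0.2), seed=1)
        assert (h.siv_power(spec)["power"] == 0.0).all()

    def test_agrees_with_high_rep_bruteforce(self):
        """Mid-range power case cross-checked against an independent
        vectorised re-simulation at 200k reps."""
        sd, thr, n_ind = 0.12, 0.2, 4
        spec = _spec(0.5, sd, n_cpgs=1, n_reps=4000,
                     predicate=h.SIVPredicate(range_threshold=thr), seed=7)
        p_hat = h.siv_power(spec)["power"].iloc[0]
        rng = np.random.default_rng(123)
        draws = np.clip(rng.normal(0.5, sd, (200_000, n_ind, 3)), 0, 1)
        means = draws.mean(axis=2)
        p_true = ((means.max(axis=1) - means.min(axis=1)) >= thr).mean()
        se = np.sqrt(p_hat * (1 - p_hat) / 4000 + p_true * (1 - p_true) / 200_000)
        assert abs(p_hat - p_true) < 3 * se

    def test_monotone_in_threshold_and_scale(self):
        powers_thr = []
        for thr in (0.05, 0.15, 0.3):
            spec = _spec(0.5, 0.1, n_cpgs=1, predicate=h.SIVPredicate(range_threshold=thr), seed=3)
            powers_thr.append(h.siv_power(spec)["power"].iloc[0])
        assert powers_thr[0] >= powers_thr[1] >= powers_thr[2]
        powers_sd = []
        for sd in (0.02, 0.08, 0.2):
            spec = _spec(0.5, sd, n_cpgs=1, predicate=h.SIVPredicate(range_threshold=0.2), seed=3)
            powers_sd.append(h.siv_power(spec)["power"].iloc[0])
        assert powers_sd[0] <= powers_sd[1] <= powers_sd[2]

    def test_seed_determinism_and_summary(self):
        spec = _spec(0.5, 0.1, predicate=h.SIVPredicate(range_threshold=0.2), seed=9)
        a = h.siv_power(spec)
        b = h.siv_power(_spec(0.5, 0.1, predicate=h.SIVPredicate(range_threshold=0.2), seed=9))
        assert a["power"].equals(b["power"])
        assert set(a.attrs["summary"]) == {"mean", "median", "iqr"}

    def test_non_psd_rejected(self):
        idx = ["cg0"]
        mu = pd.DataFrame(np.full((1, 3), 0.5), index=idx)
        bad = -0.1 * np.eye(3)
        with pytest.raises(h.InputError):
            h.siv_power(h.PowerSimSpec(mu=mu, sigma=bad[None, :, :]))


def test_estimate_power_spec_covariance_matches_numpy_oracle():
    rng = np.random.default_rng(11)
    idx = [f"cg{i}" for i in range(4)]
    cols = [f"i{j}" for j in range(9)]
    tissues = {t: pd.DataFrame(rng.uniform(0.2, 0.8, (4, 9)), index=idx, columns=cols)
               for t in ("gall_bladder", "aorta", "nerve")}
    spec = h.estimate_power_spec(tissues)
    stacked = np.stack([tissues[t].to_numpy() for t in tissues], axis=2)
    for c in range(4):
        assert np.allclose(spec.sigma[c], np.cov(stacked[c].T, ddof=1))
        assert np.allclose(spec.mu.iloc[c], stacked[c].mean(axis=0))
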