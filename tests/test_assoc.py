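"""Cluster PCA scores, covariate association models, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest

import lifetraj as lt
from lifetraj.stats import fdr_correct


def test_single_roi_cluster_score_is_centered_activity(cohort, activity):
    scores = lt.cluster_scores(activity, {"roi-000": 1})
    col = activity["roi-000"].to_numpy()
    expected = col - col.mean()
    got = scores[1].to_numpy()
    assert abs(got.mean()) < 1e-10
    r = np.corrcoef(got, expected)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_perfectly_correlated_columns_explained_by_pc1(cohort):
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, len(cohort))
    act = pd.DataFrame({"subject_id": cohort["subject_id"],
                        "r1": base, "r2": 2 * base + 5})
    scores = lt.cluster_scores(act, {"r1": 1, "r2": 1})
    sub = np.column_stack([base - base.mean(), 2 * (base - base.mean())])
    # PC1 carries all the variance: the score reproduces the submatrix
    recon = np.outer(scores[1], np.linalg.svd(sub)[2][0])
    np.testing.assert_allclose(np.abs(recon), np.abs(sub), atol=1e-8)


def test_scores_invariant_to_constant_shift(cohort, activity, pipeline_result):
    assignment = pipeline_result.full_assignment()
    s1 = lt.cluster_scores(activity, assignment)
    shifted = activity.copy()
    rois = [r for r, l in assignment.items() if l == 2]
    shifted[rois] = shifted[rois] + 7.5
    s2 = lt.cluster_scores(shifted, assignment)
    np.testing.assert_allclose(s1[2], s2[2], atol=1e-8)


def test_score_sign_tracks_cluster_mean_activity(cohort, activity, pipeline_result):
    scores = lt.cluster_scores(activity, pipeline_result.solution)
    for lab in scores.columns:
        rois = [r for r, l in pipeline_result.solution.assignment.items() if l == lab]
        mean_act = activity[rois].mean(axis=1).to_numpy()
        assert np.corrcoef(scores[lab], mean_act)[0, 1] > 0


def test_score_recovers_planted_subject_offsets():
    coh = lt.generate_cohort(300, seed=51)
    truth = lt.default_ground_truth(60, noise_sd=0.1)
    act, _ = lt.generate_activity(coh, truth, seed=52, subject_sd=0.3)
    lab4 = [f"roi-{j:03d}" for j, l in enumerate(truth.roi_assignment) if l == 4]
    scores = lt.cluster_scores(act, {r: 4 for r in lab4})
    # the shared offset dominates PC1
    sub = act[lab4].to_numpy()
    offs = (sub - sub.mean(axis=0)).mean(axis=1)
    assert abs(np.corrcoef(scores[4], offs)[0, 1]) > 0.9


def test_linear_association_recovered():
    rng = np.random.default_rng(7)
    n = 400
    age = rng.uniform(6, 82, n)
    sex = rng.integers(0, 2, n).astype(float)
    covariate = rng.normal(0, 1, n)             # independent of age
    score = 0.5 * covariate + rng.normal(0, 0.5, n)
    res = lt.gam_association(score, covariate, age, sex)
    assert res.p < 1e-10
    assert res.edf == pytest.approx(1.0, abs=0.5)
    assert res.direction == "increasing"


def test_collinear_covariate_does_not_crash():
    rng = np.random.default_rng(8)
    n = 300
    age = rng.uniform(6, 82, n)
    score = np.sin(age / 10) + rng.normal(0, 0.3, n)
    res = lt.gam_association(score, age.copy(), age, rng.integers(0, 2, n))
    assert res.p == 1.0 and res.F == 0.0
    with pytest.raises(ValueError):
        lt.gam_association(score, np.full(n, 3.0), age, np.zeros(n))
    with pytest.raises(ValueError):
        lt.gam_association(score[:30], age[:30], age[:30], np.zeros(30))


def test_bh_hand_computation_and_edges():
    q = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert fdr_correct(np.array([0.2]))[0] == pytest.approx(0.2)
    np.testing.assert_allclose(fdr_correct(np.ones(5)), 1.0)
    # explicit family larger than the supplied tests
    q = fdr_correct(np.array([0.001, 0.01]), family_size=10)
    np.testing.assert_allclose(q, [0.01, 0.05])
    with pytest.raises(ValueError):
        fdr_correct(np.array([0.0, 0.5]))
    with pytest.raises(ValueError):
        fdr_correct(np.array([0.5, 1.5]))


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(3)
    p = rng.uniform(1e-6, 1, 40)
    np.testing.assert_allclose(fdr_correct(p),
                               multipletests(p, method="fdr_bh")[1], atol=1e-12)


def test_bh_q_monotone_in_p():
    rng = np.random.default_rng(4)
    p = rng.uniform(1e-6, 1, 25)
    q = fdr_correct(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


def test_bh_controls_false_discovery_proportion():
    """Across replicate families, mean FDP stays at or below alpha."""
    rng = np.random.default_rng(5)
    alpha, m, m0 = 0.05, 20, 10
    fdps = []
    for _ in range(1000):
        p_null = rng.uniform(0, 1, m0)
        p_alt = rng.beta(0.05, 8, m - m0)       # strong signals
        p = np.clip(np.r_[p_null, p_alt], 1e-12, 1)
        q = fdr_correct(p)
        rej = q < alpha
        fdps.append(rej[:m0].sum() / max(rej.sum(), 1))
    assert np.mean(fdps) <= alpha + 0.01


def test_run_associations_detects_planted_coupling(cohort, truth, activity,
                                                   pipeline_result):
    cov = lt.generate_covariates(cohort, truth, seed=3, activity=activity,
                                 coupled_cluster=4, partial_r=0.4)
    scores = lt.cluster_scores(activity, pipeline_result.full_assignment())
    res = lt.run_associations(scores, cov, cohort,
                              covariate_names=["task_memory", "cvlt_learning",
                                               "matrices", "vocabulary"],
                              family_size=24)
    assert (res["family"] == 24).all()
    hit = res[(res.cluster == 4) & (res.covariate == "task_memory")]
    assert hit["significant"].item()
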