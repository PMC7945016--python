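"""Synthetic-data generators: determinism, fidelity, planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lifetraj as lt
from lifetraj.synthdata import SHAPES, ShapeSpec


def test_cohort_respects_range_and_determinism():
    c1 = lt.generate_cohort(540, 6, 82, seed=1)
    c2 = lt.generate_cohort(540, 6, 82, seed=1)
    assert len(c1) == 540
    assert c1["age"].between(6, 82).all()
    assert (c1["mean_motion"] >= 0).all()
    assert c1["subject_id"].is_unique
    pd.testing.assert_frame_equal(c1, c2)
    assert not c1.equals(lt.generate_cohort(540, 6, 82, seed=2))


def test_cohort_degenerate_range_and_errors():
    c = lt.generate_cohort(2, 10, 10.0001, seed=1)
    assert np.allclose(c["age"], 10, atol=1e-3)
    with pytest.raises(ValueError):
        lt.generate_cohort(1, 6, 82, seed=1)
    with pytest.raises(ValueError):
        lt.generate_cohort(10, 50, 50, seed=1)


def test_motion_is_u_shaped_and_steeper_in_childhood():
    c = lt.generate_cohort(4000, seed=3)
    m_child = c.loc[c.age < 12, "mean_motion"].mean()
    m_mid = c.loc[c.age.between(30, 50), "mean_motion"].mean()
    m_old = c.loc[c.age > 72, "mean_motion"].mean()
    assert m_child > m_mid and m_old > m_mid
    assert (m_child - m_mid) > (m_old - m_mid)  # steeper on the young side


def test_zero_noise_activity_equals_canonical_curves():
    coh = lt.generate_cohort(50, seed=4)
    truth = lt.default_ground_truth(12, noise_sd=0.0)
    act, _ = lt.generate_activity(coh, truth, seed=5)
    a = (coh["age"].to_numpy() - 6) / 76
    for j, lab in enumerate(truth.roi_assignment):
        expected = truth.shape_per_cluster[int(lab)].value(a)
        np.testing.assert_allclose(act[f"roi-{j:03d}"], expected, atol=0)
    # null regions are exactly zero
    null_cols = [f"roi-{j:03d}" for j, l in enumerate(truth.roi_assignment) if l == 0]
    assert (act[null_cols].to_numpy() == 0).all()


def test_per_cluster_mean_curves_match_generating_shapes(cohort, truth, activity):
    """Averaging noisy columns per planted cluster recovers the shapes."""
    a = (cohort["age"].to_numpy() - 6) / 76
    bins = np.digitize(a, np.linspace(0, 1, 16)[1:-1])
    for lab, spec in truth.shape_per_cluster.items():
        if lab == 0:
            continue
        cols = [f"roi-{j:03d}" for j, l in enumerate(truth.roi_assignment) if l == lab]
        per_subject = activity[cols].to_numpy().mean(axis=1)
        # mean curve over age: average regions, then subjects within age bins
        curve = np.array([per_subject[bins == b].mean() for b in range(15)])
        expected = np.array([spec.value(a[bins == b]).mean() for b in range(15)])
        r = np.corrcoef(curve, expected)[0, 1]
        assert r > 0.95, f"cluster {lab}: r={r:.3f}"


def test_activity_determinism_and_noise_validation(cohort):
    truth = lt.default_ground_truth(24, noise_sd=0.1)
    a1, _ = lt.generate_activity(cohort, truth, seed=9)
    a2, _ = lt.generate_activity(cohort, truth, seed=9)
    pd.testing.assert_frame_equal(a1, a2)
    with pytest.raises(ValueError):
        lt.GroundTruth(truth.roi_assignment, truth.shape_per_cluster, noise_sd=-0.1)


def test_trials_chance_level_and_ceiling():
    coh = lt.generate_cohort(8, seed=6)
    flat0 = ShapeSpec("null", 0, 0)
    trials = lt.generate_trials(coh, n_old=4000, perf_curve=flat0, seed=7,
                                p_no_response=0.0)
    scores = lt.score_all(trials)
    assert abs(scores["corrected_index"].mean()) < 0.02
    # maximal (constant 1) signal drives the index to 1
    t2 = lt.generate_trials(coh, n_old=50, perf_curve=ShapeSpec("monotonic_up", 0.0, 1.0),
                            seed=8, p_no_response=0.0)
    s2 = lt.score_all(t2)
    assert (s2["corrected_index"] == 1.0).all()


def test_trials_recover_inverted_u_performance_curve():
    coh = lt.generate_cohort(300, seed=21)
    trials = lt.generate_trials(coh, n_old=100, seed=22)
    scores = lt.score_all(trials).merge(coh, on="subject_id")
    from lifetraj.gam import SmoothDesign
    des = SmoothDesign(scores["age"].to_numpy(), scores["sex"].to_numpy())
    y = scores["corrected_index"].to_numpy()
    fit = des.fit(y)
    F, p = des.smooth_test(y)
    assert p < 1e-6 and fit.edf_smooth > 1.5
    grid = np.linspace(6, 82, 100)
    curve = des.curve(fit, grid)
    assert curve.argmax() not in (0, 99)  # peak in the interior: inverted U


def test_expansion_map_is_positively_skewed_and_enrichment_planted():
    truth = lt.default_ground_truth(120, noise_sd=0.1)
    skews = []
    for seed in range(30):
        maps = lt.generate_maps(truth, enriched_cluster=4, effect=0.0, seed=seed)
        skews.append(stats.skew(maps["expansion"]))
    assert np.mean(skews) > 0.5
    maps = lt.generate_maps(truth, enriched_cluster=4, effect=10.0, seed=1)
    lab = truth.roi_assignment
    for kind in ("flexibility", "gradient", "expansion"):
        inside = maps.loc[lab == 4, kind].mean()
        outside = maps.loc[lab != 4, kind].mean()
        assert inside > outside + 5


def test_covariates_hit_target_age_r2():
    coh = lt.generate_cohort(540, seed=31)
    cov = lt.generate_covariates(coh, seed=32)
    from lifetraj.gam import SmoothDesign
    des = SmoothDesign(coh["age"].to_numpy(), coh["sex"].to_numpy())
    for name, target in [("gm_ic1", 0.86), ("gm_ic2", 0.46)]:
        y = cov[name].to_numpy()
        fit = des.fit(y)
        r2 = 1 - fit.rss / np.sum((y - y.mean()) ** 2)
        assert r2 == pytest.approx(target, abs=0.05), name


def test_write_dataset_round_trip(tmp_path, cohort, truth, activity):
    lt.synthdata.write_dataset(tmp_path, cohort, activity=activity, truth=truth)
    back = pd.read_csv(tmp_path / "activity.csv")
    assert back.shape == activity.shape
    np.testing.assert_allclose(back["roi-000"], activity["roi-000"])
    assert (tmp_path / "truth.json").exists()
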