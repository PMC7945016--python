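"""Cluster activity scores and their association with cognition and
grey-matter variation.

Each subject's activity within a cluster is summarized as the projection on
the first principal component of the (column-centered) subjects x ROIs
submatrix, oriented to correlate positively with the cluster's mean
activity.  Associations between these scores and cognitive or grey-matter
covariates are tested with additive models ``score ~ s(age) + s(covariate)
+ sex`` — age enters as a smooth so that the covariate effect is assessed
over and above any (possibly nonlinear) age trend — and corrected across an
explicitly sized family of tests with the Benjamini–Hochberg procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gam import AdditiveGAM
from .stats import fdr_correct

__all__ = ["cluster_scores", "gam_association", "run_associations",
           "fdr_correct", "AssociationResult"]


def cluster_scores(activity, solution, include_cluster0=None):
    """First-principal-component subject scores per cluster.

    Returns a DataFrame indexed by subject with one column per cluster
    label.  Scores are centered; the sign is chosen so each score
    correlates positively with the mean activity across the cluster's
    regions.  ``solution`` may be a :class:`~lifetraj.cluster.
    ClusterSolution` or any roi_id -> label mapping (label 0 regions, if
    present in a mapping, get a score as well: the conventional FDR
    families count the no-effect cluster among the tested clusters).
    """
    assignment = solution if isinstance(solution, dict) else solution.assignment
    labels = sorted(set(assignment.values()))
    out = pd.DataFrame(index=pd.Index(activity["subject_id"], name="subject_id"))
    for lab in labels:
        rois = [r for r, c in assignment.items() if c == lab]
        if not rois:
            raise ValueError(f"cluster {lab} has no regions")
        sub = activity[rois].to_numpy(dtype=float)
        subc = sub - sub.mean(axis=0)
        _, _, Vt = np.linalg.svd(subc, full_matrices=False)
        score = subc @ Vt[0]
        mean_act = sub.mean(axis=1)
        if np.corrcoef(score, mean_act - mean_act.mean())[0, 1] < 0:
            score = -score
        out[lab] = score
    return out


@dataclass
class AssociationResult:
    cluster: object
    covariate: str
    F: float
    p: float
    edf: float
    direction: str
    q: float = np.nan
    family: int = 0


def gam_association(score, covariate, age, sex, gamma=2.0, k=10):
    """Test one cluster-score/covariate association, controlling age + sex.

    Fits ``score ~ s(age) + s(covariate) + sex`` with REML-selected
    smoothness (wiggliness multiplier ``gamma``) and returns the exact F
    test of the covariate smooth from the unpenalized nested comparison,
    the penalized smooth's effective degrees of freedom, and a coarse
    direction summary of the fitted partial curve.
    """
    score = np.asarray(score, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ok = np.isfinite(score) & np.isfinite(covariate) & np.isfinite(age) & np.isfinite(sex)
    if ok.sum() < 50:
        raise ValueError("fewer than 50 complete cases")
    score, covariate, age, sex = score[ok], covariate[ok], age[ok], sex[ok]
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant")
    model = AdditiveGAM(score, [age, covariate], linear_vars=[sex], k=k, gamma=gamma)
    F, p = model.smooth_test(1)
    edf = max(model.edf_smooth[1], 1.0)
    grid = np.linspace(covariate.min(), covariate.max(), 50)
    part = model.partial_curve(1, grid)
    span = np.ptp(part)
    if span < 1e-12:
        direction = "flat"
    elif part[-1] - part[0] > 0.5 * span:
        direction = "increasing"
    elif part[0] - part[-1] > 0.5 * span:
        direction = "decreasing"
    else:
        direction = "nonmonotone"
    return AssociationResult(cluster=None, covariate="", F=F, p=p,
                             edf=edf, direction=direction)


def run_associations(scores, covariates, subjects, covariate_names=None,
                     family_size=None, gamma=2.0, alpha=0.05):
    """Test every cluster score against every covariate, with FDR.

    ``scores`` is the wide table from :func:`cluster_scores`, ``covariates``
    a subject_id-keyed table of test scores or component loadings.
    ``family_size`` is the explicit FDR family size (defaults to the number
    of tests run here).  Returns a tidy DataFrame.
    """
    if covariate_names is None:
        covariate_names = [c for c in covariates.columns if c != "subject_id"]
    merged = covariates.set_index("subject_id").join(
        subjects.set_index("subject_id")[["age", "sex"]], how="inner")
    merged = merged.loc[scores.index]
    rows = []
    for lab in scores.columns:
        for name in covariate_names:
            r = gam_association(scores[lab].to_numpy(), merged[name].to_numpy(),
                                merged["age"].to_numpy(), merged["sex"].to_numpy(),
                                gamma=gamma)
            r.cluster, r.covariate = lab, name
            rows.append(r)
    m = family_size if family_size is not None else len(rows)
    q = fdr_correct(np.array([r.p for r in rows]), family_size=m)
    for r, qi in zip(rows, q):
        r.q, r.family = float(qi), m
    return pd.DataFrame([{
        "cluster": r.cluster, "covariate": r.covariate, "F": r.F, "p": r.p,
        "q": r.q, "edf": r.edf, "direction": r.direction, "family": r.family,
        "significant": r.q < alpha,
    } for r in rows])
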