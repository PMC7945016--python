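"""Synthetic cohort generator with planted lifespan-trajectory structure.

Every input the analysis pipeline consumes can be simulated here with known
ground truth: a cohort (age, sex, in-scanner motion), an encoding-activity
matrix whose regions follow canonical lifespan shapes, a subsequent-memory
trial table, ROI-level brain-organization maps, and subject-level cognitive
and grey-matter covariates.  All generators are deterministic given a seed.

Canonical trajectory shapes are fixed closed-form functions of normalized
age ``a = (age - age_min) / (age_max - age_min)``:

``monotonic_up``          ``a``                      weak lifelong increase
``u_shape``               ``(2a - 1)^2``             U shape (dip mid-life)
``weak_inverted_u``       ``0.4 (1 - (2a - 1)^2)``   shallow inverted U
``steep_inverted_u``      ``1 - (2a - 1)^2``         steep inverted U
``developmental_plateau`` ``min(a / 0.3, 1)``        childhood rise, plateau
``null``                  ``0``                      no age dependence

A region's expected activity is ``baseline + amplitude * shape(a)``; noise
is additive Gaussian.  Regions planted in the ``null`` cluster (label 0)
have zero mean and no age dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ShapeSpec", "GroundTruth", "SHAPES",
    "generate_cohort", "default_ground_truth", "generate_activity",
    "generate_roi_table", "generate_trials", "generate_maps",
    "generate_covariates", "write_dataset",
]

SHAPES = {
    "monotonic_up": lambda a: a,
    "u_shape": lambda a: (2 * a - 1) ** 2,
    "weak_inverted_u": lambda a: 0.4 * (1 - (2 * a - 1) ** 2),
    "steep_inverted_u": lambda a: 1 - (2 * a - 1) ** 2,
    "developmental_plateau": lambda a: np.minimum(a / 0.3, 1.0),
    "null": lambda a: np.zeros_like(a),
}


@dataclass(frozen=True)
class ShapeSpec:
    """A canonical trajectory: named shape scaled and shifted.

    ``amplitude`` and ``baseline`` are in activity units (percent signal
    change of the source-vs-item contrast).  ``null`` shapes must have zero
    amplitude and baseline.
    """

    name: str
    amplitude: float = 0.5
    baseline: float = 0.0

    def __post_init__(self):
        if self.name not in SHAPES:
            raise ValueError(f"unknown shape {self.name!r}; one of {sorted(SHAPES)}")
        if self.name == "null" and (self.amplitude != 0 or self.baseline != 0):
            object.__setattr__(self, "amplitude", 0.0)
            object.__setattr__(self, "baseline", 0.0)

    def value(self, a_norm):
        """Expected activity at normalized age ``a_norm`` in [0, 1]."""
        a = np.asarray(a_norm, dtype=float)
        return self.baseline + self.amplitude * SHAPES[self.name](a)


@dataclass
class GroundTruth:
    """Planted cluster structure behind a simulated activity matrix."""

    roi_assignment: np.ndarray            # per-ROI planted label, 0 = null
    shape_per_cluster: dict               # label -> ShapeSpec
    noise_sd: float

    def __post_init__(self):
        self.roi_assignment = np.asarray(self.roi_assignment, dtype=int)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for lab in np.unique(self.roi_assignment):
            if lab not in self.shape_per_cluster:
                raise ValueError(f"no shape defined for planted cluster {lab}")

    def to_json(self):
        return json.dumps({
            "roi_assignment": self.roi_assignment.tolist(),
            "shape_per_cluster": {str(k): asdict(v) for k, v in self.shape_per_cluster.items()},
            "noise_sd": self.noise_sd,
        }, indent=1)


# default planted composition at desk scale: one null block plus the five
# canonical shapes, with sizes loosely echoing the empirical solution's
# strongly unequal cluster sizes
_DEFAULT_SHAPES = {
    0: ShapeSpec("null", 0.0, 0.0),
    1: ShapeSpec("monotonic_up", 0.5, 0.0),
    2: ShapeSpec("u_shape", 0.5, -0.3),
    3: ShapeSpec("weak_inverted_u", 0.5, 0.1),
    4: ShapeSpec("steep_inverted_u", 0.5, 0.15),
    5: ShapeSpec("developmental_plateau", 0.5, 0.1),
}
_DEFAULT_FRACTIONS = {0: 20 / 120, 1: 35 / 120, 2: 20 / 120,
                      3: 20 / 120, 4: 15 / 120, 5: 10 / 120}


def default_ground_truth(n_rois=120, noise_sd=0.125, shapes=None, fractions=None):
    """Planted truth with a null block and five canonical shape clusters.

    The default noise level is 0.25x the shape amplitude (0.125 on
    amplitude 0.5), the regime in which the pipeline is expected to recover
    the planted partition essentially perfectly.
    """
    shapes = dict(_DEFAULT_SHAPES if shapes is None else shapes)
    fractions = dict(_DEFAULT_FRACTIONS if fractions is None else fractions)
    labels = sorted(shapes)
    counts = {lab: int(round(fractions.get(lab, 0) * n_rois)) for lab in labels}
    # fix rounding drift on the largest cluster
    drift = n_rois - sum(counts.values())
    biggest = max(counts, key=lambda c: counts[c])
    counts[biggest] += drift
    assignment = np.concatenate([np.full(counts[lab], lab) for lab in labels])
    return GroundTruth(assignment, shapes, noise_sd)


def _rng(seed):
    if seed is None:
        raise ValueError("an integer seed is required for reproducibility")
    return np.random.default_rng(seed)


def generate_cohort(n, age_min=6.0, age_max=82.0, seed=0, age_distribution="uniform"):
    """Simulate a cross-sectional cohort.

    Ages are drawn from a configurable distribution over ``[age_min,
    age_max]`` (uniform by default), sexes are balanced in expectation
    (coded 0/1), and the mean in-scanner motion summary (DVARS-like) follows
    a U-shaped age profile with a steeper slope in childhood than in older
    age.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not age_min < age_max:
        raise ValueError("empty age range")
    rng = _rng(seed)
    if age_distribution == "uniform":
        age = rng.uniform(age_min, age_max, n)
    else:
        raise ValueError(f"unknown age distribution {age_distribution!r}")
    sex = rng.integers(0, 2, n)
    # motion: steep fall through childhood/adolescence, shallow rise late
    motion_mean = (0.3
                   + 0.6 * np.clip((20.0 - age) / 14.0, 0, None) ** 1.5
                   + 0.25 * np.clip((age - 50.0) / 32.0, 0, None) ** 2)
    mean_motion = np.maximum(0.0, motion_mean + rng.normal(0, 0.08, n))
    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "mean_motion": mean_motion,
    })


def _norm_age(age, age_min=None, age_max=None):
    age = np.asarray(age, dtype=float)
    lo = age.min() if age_min is None else age_min
    hi = age.max() if age_max is None else age_max
    return (age - lo) / (hi - lo)


def generate_activity(cohort, truth, seed=0, n_rois=None, subject_sd=0.0,
                      age_min=6.0, age_max=82.0):
    """Simulate the subjects x ROIs encoding-contrast matrix.

    ``cell(s, r) = shape_r(a_s) + N(0, noise_sd)``, with shapes evaluated at
    the subject's normalized age.  ``subject_sd`` optionally adds a shared
    per-subject offset to every non-null region of a cluster, giving the
    matrix a trait-like between-subject dimension (used when downstream
    covariate couplings are wanted).  Returns ``(activity, truth)``.
    """
    if n_rois is not None and n_rois != len(truth.roi_assignment):
        raise ValueError("n_rois does not match the planted assignment length")
    n_clusters = len([c for c in truth.shape_per_cluster if c != 0])
    if len(truth.roi_assignment) < n_clusters:
        raise ValueError("fewer ROIs than planted clusters")
    rng = _rng(seed)
    a = _norm_age(cohort["age"].to_numpy(), age_min, age_max)
    n, m = len(cohort), len(truth.roi_assignment)
    act = np.empty((n, m))
    offsets = {}
    for lab, spec in truth.shape_per_cluster.items():
        offsets[lab] = (rng.normal(0, subject_sd, n) if subject_sd > 0 and lab != 0
                        else np.zeros(n))
    for j, lab in enumerate(truth.roi_assignment):
        spec = truth.shape_per_cluster[int(lab)]
        act[:, j] = spec.value(a) + offsets[int(lab)]
    act += rng.normal(0, truth.noise_sd, size=(n, m))
    cols = [f"roi-{j:03d}" for j in range(m)]
    out = pd.DataFrame(act, columns=cols)
    out.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return out, truth


def generate_roi_table(n_rois, subcortical_fraction=0.12, seed=0):
    """ROI metadata: id, hemisphere, cortical flag."""
    rng = _rng(seed)
    n_sub = int(round(subcortical_fraction * n_rois))
    cortical = np.ones(n_rois, dtype=bool)
    if n_sub:
        cortical[rng.choice(n_rois, size=n_sub, replace=False)] = False
    return pd.DataFrame({
        "roi_id": [f"roi-{j:03d}" for j in range(n_rois)],
        "hemisphere": ["L" if j % 2 == 0 else "R" for j in range(n_rois)],
        "cortical": cortical,
    })


def generate_trials(cohort, n_old=100, perf_curve=None, seed=0,
                    p_no_response=0.02, age_min=6.0, age_max=82.0):
    """Simulate old-item test trials of the three-question memory test.

    Each old item is probed with Q1 (recognized?), Q2 (remember the
    associated action?) and, when both are affirmed, the two-alternative
    source question Q3, which is correct with probability ``0.5 + 0.5 *
    signal(age)``.  Recognition and association rates also scale with the
    signal so that a maximal signal drives the guess-corrected index to 1
    and a zero signal leaves it at 0 in expectation.  The signal's lifespan
    profile is ``perf_curve`` (default: a steep inverted U, mimicking the
    inverted-U source-memory performance curve over ages 6-82).
    """
    if n_old < 6:
        raise ValueError("need at least 6 old trials per subject")
    if perf_curve is None:
        perf_curve = ShapeSpec("steep_inverted_u", amplitude=0.6, baseline=0.05)
    rng = _rng(seed)
    a = _norm_age(cohort["age"].to_numpy(), age_min, age_max)
    signal = np.clip(perf_curve.value(a), 0.0, 1.0)
    rows = []
    for s_id, sig in zip(cohort["subject_id"], signal):
        p1 = 0.7 + 0.3 * sig
        p2 = 0.5 + 0.5 * sig
        p3 = 0.5 + 0.5 * sig
        for t in range(n_old):
            q1 = q2 = q3 = None
            if rng.random() < p_no_response:
                pass                                   # no response at Q1
            elif rng.random() >= p1:
                q1 = "no"
            else:
                q1 = "yes"
                q2 = "yes" if rng.random() < p2 else "no"
                if q2 == "yes":
                    q3 = "correct" if rng.random() < p3 else "incorrect"
            rows.append((s_id, t, True, q1, q2, q3))
    return pd.DataFrame(rows, columns=["subject_id", "trial", "is_old", "q1", "q2", "q3"])


def generate_maps(truth, enriched_cluster, effect=1.0, seed=0,
                  kinds=("flexibility", "gradient", "expansion"), roi_table=None):
    """ROI-level brain-organization maps with one planted enrichment.

    ``flexibility``- and ``gradient``-like maps are standard normal plus
    ``effect`` inside the enriched cluster; the ``expansion``-like map has
    an exponential (positively skewed) marginal, motivating the rank
    transform applied before enrichment testing.  If ``roi_table`` is given,
    gradient and expansion values are missing for subcortical ROIs (those
    maps exist only for the cortical surface).
    """
    if enriched_cluster not in truth.shape_per_cluster:
        raise ValueError(f"cluster {enriched_cluster} not planted in the truth")
    rng = _rng(seed)
    m = len(truth.roi_assignment)
    ind = (truth.roi_assignment == enriched_cluster).astype(float)
    out = pd.DataFrame({"roi_id": [f"roi-{j:03d}" for j in range(m)]})
    for kind in kinds:
        if kind == "expansion":
            vals = rng.exponential(1.0, m) + effect * ind
        else:
            vals = rng.normal(0.0, 1.0, m) + effect * ind
        out[kind] = vals
    if roi_table is not None:
        sub = ~roi_table["cortical"].to_numpy()
        for kind in kinds:
            if kind != "flexibility":
                out.loc[sub, kind] = np.nan
    return out


_COGNITION_SHAPES = {
    # lifespan profiles of the four test scores: task memory and verbal
    # learning peak in adulthood, matrix reasoning (fluid) likewise,
    # vocabulary (crystallized) rises through development then plateaus
    "task_memory": ShapeSpec("steep_inverted_u", 1.0, 0.0),
    "cvlt_learning": ShapeSpec("steep_inverted_u", 1.0, 0.0),
    "matrices": ShapeSpec("steep_inverted_u", 1.0, 0.0),
    "vocabulary": ShapeSpec("developmental_plateau", 1.0, 0.0),
}


def generate_covariates(cohort, truth=None, seed=0, activity=None,
                        coupled_cluster=None, partial_r=0.0,
                        coupled_covariates=("task_memory",),
                        gm_age_r2=(0.86, 0.46), cognition_age_r2=0.5,
                        age_min=6.0, age_max=82.0):
    """Subject-level cognitive scores and grey-matter component loadings.

    Two grey-matter components are produced: a dominant mode decreasing
    monotonically across the lifespan (age R^2 target ``gm_age_r2[0]``,
    default 0.86) and a second mode with an inverted-U age profile (default
    R^2 0.46).  Four cognitive scores follow canonical lifespan shapes.

    If ``activity`` and ``coupled_cluster`` are given, the covariates named
    in ``coupled_covariates`` receive an age-independent component aligned
    with the coupled cluster's first principal component of activity so
    that the partial correlation given age is ``partial_r``.
    """
    rng = _rng(seed)
    a = _norm_age(cohort["age"].to_numpy(), age_min, age_max)
    n = len(cohort)

    def with_target_r2(signal, r2):
        v = float(np.var(signal))
        if r2 <= 0:
            return rng.normal(0, 1, n)
        noise_sd = np.sqrt(v * (1 - r2) / r2)
        return signal + rng.normal(0, noise_sd, n)

    out = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})
    for name, spec in _COGNITION_SHAPES.items():
        out[name] = with_target_r2(spec.value(a), cognition_age_r2)
    out["gm_ic1"] = with_target_r2(-a, gm_age_r2[0])
    out["gm_ic2"] = with_target_r2(SHAPES["steep_inverted_u"](a), gm_age_r2[1])

    if partial_r and activity is not None and coupled_cluster is not None:
        if truth is None:
            raise ValueError("coupling requires the ground truth")
        rois = [f"roi-{j:03d}" for j, lab in enumerate(truth.roi_assignment)
                if lab == coupled_cluster]
        sub = activity[rois].to_numpy()
        subc = sub - sub.mean(axis=0)
        _, _, Vt = np.linalg.svd(subc, full_matrices=False)
        score = subc @ Vt[0]
        # residualize on age (cubic fit suffices for the canonical shapes)
        A = np.vander(a, 4)
        score = score - A @ np.linalg.lstsq(A, score, rcond=None)[0]
        z = score / score.std()
        # rebuild the coupled covariates so their entire age-independent
        # part has correlation partial_r with the cluster score
        for name in coupled_covariates:
            spec = _COGNITION_SHAPES[name]
            signal = spec.value(a)
            r2 = cognition_age_r2
            resid_sd = np.sqrt(float(np.var(signal)) * (1 - r2) / r2) if r2 > 0 else 1.0
            eps = rng.normal(0, 1, n)
            out[name] = signal + resid_sd * (partial_r * z
                                             + np.sqrt(1 - partial_r**2) * eps)
    return out


def write_dataset(outdir, cohort, activity=None, truth=None, trials=None,
                  maps=None, covariates=None, roi_table=None):
    """Write the simulated tables as plain CSV (plus truth.json)."""
    import pathlib
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "subjects.csv", index=False)
    if activity is not None:
        activity.to_csv(outdir / "activity.csv", index=False)
    if trials is not None:
        trials.to_csv(outdir / "trials.csv", index=False)
    if maps is not None:
        maps.to_csv(outdir / "maps.csv", index=False)
    if covariates is not None:
        covariates.to_csv(outdir / "covariates.csv", index=False)
    if roi_table is not None:
        roi_table.to_csv(outdir / "rois.csv", index=False)
    if truth is not None:
        (outdir / "truth.json").write_text(truth.to_json())
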