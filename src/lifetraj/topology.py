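"""Permutation tests relating cluster membership to brain-organization maps.

For each external ROI-level map (task flexibility, principal connectivity
gradient, evolutionary cortical expansion) and each cluster, the observed
statistic is the cluster's mean map value minus the mean over all other
effect-bearing regions.  Significance comes from a label-permutation null:
cluster labels are randomly reassigned over regions (preserving cluster
sizes), the statistic is recomputed each time, and the two-sided p-value is
``(1 + #{|null| >= |observed|}) / (n_perm + 1)``.  Heavily skewed maps (the
expansion map has a roughly exponential marginal) are rank-transformed
before testing, which makes the result invariant to any strictly monotone
re-expression of the map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .stats import fdr_correct

__all__ = ["rank_transform", "permutation_enrichment", "run_enrichment"]


def rank_transform(values):
    """Replace values by mid-ranks (ties share the mean rank); NaN kept."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    out[ok] = rankdata(v[ok])
    return out


def _cluster_stats(values, onehot, counts):
    """Mean-in-cluster minus mean-elsewhere for every cluster.

    ``values`` may be 2-D (permutations in rows)."""
    total = values.sum(axis=-1, keepdims=True)
    sums = values @ onehot
    n = values.shape[-1]
    other = (total - sums) / (n - counts)
    return sums / counts - other


def permutation_enrichment(values, labels, n_perm=10000, seed=0, pairwise=False):
    """Cluster-enrichment permutation test for one map.

    ``values`` and ``labels`` are aligned per region; regions with missing
    map values are dropped (e.g. subcortical regions for surface-only
    maps).  Returns a DataFrame with one row per cluster: observed
    difference and two-sided permutation p.  With ``pairwise=True`` an
    additional DataFrame of cluster-vs-cluster mean differences (same null)
    is returned as second element.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    v = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(v)
    v, labels = v[ok], labels[ok]
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    n = len(v)
    onehot = (labels[:, None] == clusters[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    obs = _cluster_stats(v[None, :], onehot, counts)[0]
    rng = np.random.default_rng(seed)
    # permute the values (equivalent to permuting labels at fixed sizes)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    null = _cluster_stats(v[perm_idx], onehot, counts)
    p = (1 + np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0)) / (n_perm + 1)
    res = pd.DataFrame({"cluster": clusters, "observed": obs, "p": p})
    if not pairwise:
        return res
    pair_rows = []
    means = (v[None, :] @ onehot)[0] / counts
    null_means = v[perm_idx] @ onehot / counts
    for i, ci in enumerate(clusters):
        for j, cj in enumerate(clusters):
            if j <= i:
                continue
            d = means[i] - means[j]
            nd = null_means[:, i] - null_means[:, j]
            pp = (1 + np.sum(np.abs(nd) >= abs(d))) / (n_perm + 1)
            pair_rows.append({"cluster_a": ci, "cluster_b": cj,
                              "observed": d, "p": pp})
    return res, pd.DataFrame(pair_rows)


def run_enrichment(maps, solution, n_perm=10000, seed=0, family_size=None,
                   ranked_maps=("expansion",), alpha=0.05):
    """Enrichment tests for every map column against a cluster solution.

    ``maps`` has a ``roi_id`` column plus one column per map; ``solution``
    is a :class:`~lifetraj.cluster.ClusterSolution` or roi_id -> label
    mapping.  Maps named in ``ranked_maps`` are rank-transformed first.
    BH-FDR is applied across the full cluster x map family, whose size can
    be stated explicitly via ``family_size``.
    """
    assignment = solution if isinstance(solution, dict) else solution.assignment
    rois = [r for r in maps["roi_id"] if r in assignment]
    sub = maps.set_index("roi_id").loc[rois]
    labels = np.array([assignment[r] for r in rois])
    frames = []
    map_names = [c for c in maps.columns if c != "roi_id"]
    for i, name in enumerate(map_names):
        v = sub[name].to_numpy(dtype=float)
        if name in ranked_maps:
            v = rank_transform(v)
        res = permutation_enrichment(v, labels, n_perm=n_perm,
                                     seed=seed + i)
        res.insert(0, "map", name)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    m = family_size if family_size is not None else len(out)
    out["q"] = fdr_correct(out["p"].to_numpy(), family_size=m)
    out["family"] = m
    out["significant"] = out["q"] < alpha
    return out
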