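"""End-to-end clustering pipeline: fits -> flags -> derivatives -> k-medoids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import ClusterSolution, build_dissimilarity, select_k
from .trajfit import fit_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    fits: list                     # TrajectoryFit per region (all regions)
    flags: pd.DataFrame            # roi_id, effect_p, effect_q, has_effect
    derivatives: pd.DataFrame      # all regions x grid
    curves: pd.DataFrame           # all regions x grid (fitted activity)
    D: np.ndarray                  # dissimilarity among effect regions
    roi_ids: list                  # regions entering the dissimilarity
    solution: ClusterSolution

    def full_assignment(self):
        """roi_id -> label over all regions, with 0 for no-effect regions."""
        out = {r: 0 for r in self.flags["roi_id"]}
        out.update(self.solution.assignment)
        return out


def run_pipeline(activity, subjects, basis_dim=10, outlier_sd=4.0, alpha=0.05,
                 k_range=range(2, 11)):
    """Run the full trajectory-clustering analysis on tabular inputs.

    ``activity``: subject_id plus one column per region; ``subjects``:
    subject_id, age, sex (and optionally mean_motion).  Regions without
    evidence of a memory effect are excluded from the dissimilarity matrix
    (they form cluster 0); the number of clusters among the remaining
    regions is chosen by average silhouette width over ``k_range``.
    """
    fits, flags = fit_cohort(activity, subjects, basis_dim=basis_dim,
                             outlier_sd=outlier_sd, alpha=alpha)
    grid = fits[0].grid_ages
    derivs = pd.DataFrame([f.derivative for f in fits],
                          index=[f.roi_id for f in fits], columns=grid)
    curves = pd.DataFrame([f.fitted for f in fits],
                          index=[f.roi_id for f in fits], columns=grid)
    D, roi_ids = build_dissimilarity(derivs, flags["has_effect"].to_numpy())
    solution = select_k(D, roi_ids, k_range=k_range)
    return PipelineResult(fits=fits, flags=flags, derivatives=derivs,
                          curves=curves, D=D, roi_ids=roi_ids, solution=solution)
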