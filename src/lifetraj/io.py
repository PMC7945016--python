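"""Plain-text readers/writers for the pipeline's tabular artifacts."""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

__all__ = ["save_solution", "load_solution", "save_pipeline", "load_table"]


def load_table(path):
    return pd.read_csv(path)


def save_solution(solution, path):
    """Serialize a ClusterSolution to JSON."""
    payload = {
        "k": solution.k,
        "assignment": solution.assignment,
        "medoid_rois": solution.medoid_rois,
        "avg_silhouette": solution.avg_silhouette,
        "objective": solution.objective,
        "silhouette_per_roi": dict(zip(solution.roi_ids,
                                       map(float, solution.silhouette_per_roi))),
        "silhouette_profile": {str(k): v for k, v in solution.silhouette_profile.items()},
    }
    pathlib.Path(path).write_text(json.dumps(payload, indent=1))


def load_solution(path):
    from .cluster import ClusterSolution
    d = json.loads(pathlib.Path(path).read_text())
    roi_ids = list(d["assignment"])
    return ClusterSolution(
        k=d["k"], roi_ids=roi_ids, assignment=d["assignment"],
        medoid_rois=d["medoid_rois"],
        silhouette_per_roi=np.array([d["silhouette_per_roi"][r] for r in roi_ids]),
        avg_silhouette=d["avg_silhouette"], objective=d["objective"],
        silhouette_profile={int(k): v for k, v in d["silhouette_profile"].items()},
    )


def save_pipeline(result, outdir):
    """Write fits.csv, curves.csv, derivs.csv, dissimilarity.csv, solution.json."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fits = pd.DataFrame([{
        "roi_id": f.roi_id, "mean_activity": f.mean_activity, "age_F": f.age_F,
        "age_p": f.age_p, "edf": f.edf, "n_outliers_removed": f.n_outliers_removed,
    } for f in result.fits]).merge(result.flags, on="roi_id")
    fits.to_csv(outdir / "fits.csv", index=False)
    result.curves.to_csv(outdir / "curves.csv")
    result.derivatives.to_csv(outdir / "derivs.csv")
    pd.DataFrame(result.D, index=result.roi_ids,
                 columns=result.roi_ids).to_csv(outdir / "dissimilarity.csv")
    save_solution(result.solution, outdir / "solution.json")
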