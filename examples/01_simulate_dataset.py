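"""Simulate a complete study with known ground truth and write it as CSV.

Five region clusters follow canonical lifespan trajectory shapes (plus a
null block with no memory effect); subjects span ages 6-82 with balanced
sexes and a U-shaped motion profile.
"""

import lifetraj as lt

cohort = lt.generate_cohort(n=300, age_min=6, age_max=82, seed=11)
truth = lt.default_ground_truth(n_rois=120, noise_sd=0.125)
activity, truth = lt.generate_activity(cohort, truth, seed=12)
trials = lt.generate_trials(cohort, n_old=100, seed=13)
roi_table = lt.generate_roi_table(120, seed=14)
maps = lt.generate_maps(truth, enriched_cluster=4, effect=2.0, seed=15,
                        roi_table=roi_table)
covariates = lt.generate_covariates(cohort, truth, seed=16)

lt.synthdata.write_dataset("simulated_study", cohort, activity=activity,
                           truth=truth, trials=trials, maps=maps,
                           covariates=covariates, roi_table=roi_table)

sizes = {int(l): int((truth.roi_assignment == l).sum())
         for l in sorted(set(truth.roi_assignment))}
print(f"cohort: {len(cohort)} subjects, ages "
      f"{cohort.age.min():.1f}-{cohort.age.max():.1f}")
print(f"activity: {activity.shape[0]} subjects x {activity.shape[1]-1} regions")
print(f"planted cluster sizes (0 = no memory effect): {sizes}")
print("written to simulated_study/: subjects, activity, trials, maps, "
      "covariates, rois (.csv) and truth.json")
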