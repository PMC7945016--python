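"""Score the subsequent-memory test trials and apply the trial-count
exclusion.

Each old item is classified as source / item / incorrect-source / miss /
no-response from the three-question test; the guess-corrected index
(source minus incorrect-source, over all old trials) is 0 at chance and 1
at ceiling.  Subjects with fewer than 6 trials in the source or item
condition are excluded, as their encoding contrast would be unreliable.
"""

import lifetraj as lt

cohort = lt.generate_cohort(n=300, seed=11)
trials = lt.generate_trials(cohort, n_old=100, seed=13)

scores = lt.score_all(trials)
kept, excluded = lt.exclude_low_trial_subjects(scores, min_trials=6)

print(scores.head().to_string(index=False))
print(f"\nmean corrected source-memory index: "
      f"{scores.corrected_index.mean():.3f} "
      "(0 = chance on the two-alternative source question)")
print(f"excluded for <6 trials in a condition: {len(excluded)} of {len(scores)}")
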