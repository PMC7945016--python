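"""Subsequent-memory trial classification and guess-corrected scoring.

Old items at test are probed with a branching three-question procedure:
Q1 "have you seen this item?" (yes/no), then — only after a yes — Q2 "do
you remember what you were supposed to do with it?" (yes/no), then — only
after a second yes — the two-alternative source question Q3 (correct/
incorrect).  Outcomes:

* ``source``            — yes, yes, correct: item recalled with its context
* ``incorrect_source``  — yes, yes, incorrect: claims context, picks wrong
  action; behaves like item memory but is tracked separately because it
  estimates the source-guessing rate
* ``item``              — yes, no: item recognized without the association
* ``miss``              — no at Q1
* ``no_response``       — the trial ends without an answer at some stage

Because Q3 is a two-alternative forced choice, pure guessing after
(yes, yes) yields correct and incorrect source responses at equal rates, so
``(n_source - n_incorrect_source) / n_old`` is a proportional source-memory
index corrected for guessing: 0 at chance, 1 when every old item yields a
correct source judgement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES", "MemoryScore", "classify_trial", "score_subject",
    "score_all", "exclude_low_trial_subjects", "valid_response_patterns",
]

CATEGORIES = ("source", "item", "incorrect_source", "miss", "no_response")

_YN = {"yes": "yes", "no": "no", True: "yes", False: "no", 1: "yes", 0: "no"}
_Q3 = {"correct": "correct", "incorrect": "incorrect",
       True: "correct", False: "incorrect", 1: "correct", 0: "incorrect"}


def _norm(value, table):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    try:
        return table[value]
    except (KeyError, TypeError):
        raise ValueError(f"unrecognized response {value!r}") from None


def classify_trial(is_old, q1, q2=None, q3=None):
    """Map one old-item test trial to its memory outcome category.

    Raises ``ValueError`` for responses inconsistent with the branching
    procedure (an answer to Q2 without a yes at Q1, or to Q3 without a yes
    at Q2) and for new-item trials, which carry no subsequent-memory label.
    """
    if not is_old:
        raise ValueError("only old-item trials have a subsequent-memory outcome")
    q1, q2 = _norm(q1, _YN), _norm(q2, _YN)
    q3 = _norm(q3, _Q3)
    if q1 != "yes" and q2 is not None:
        raise ValueError("Q2 answered although Q1 was not yes")
    if q2 != "yes" and q3 is not None:
        raise ValueError("Q3 answered although Q2 was not yes")
    if q1 is None:
        return "no_response"
    if q1 == "no":
        return "miss"
    if q2 is None:
        return "no_response"
    if q2 == "no":
        return "item"
    if q3 is None:
        return "no_response"
    return "source" if q3 == "correct" else "incorrect_source"


def valid_response_patterns():
    """All (q1, q2, q3) combinations consistent with the branching task."""
    pats = [(None, None, None), ("no", None, None), ("yes", None, None),
            ("yes", "no", None), ("yes", "yes", None),
            ("yes", "yes", "correct"), ("yes", "yes", "incorrect")]
    return pats


@dataclass(frozen=True)
class MemoryScore:
    """Per-subject outcome counts and the corrected source-memory index."""

    n_source: int
    n_item: int
    n_incorrect_source: int
    n_miss: int
    n_no_response: int
    n_old: int

    @property
    def corrected_index(self):
        return (self.n_source - self.n_incorrect_source) / self.n_old

    @property
    def n_item_condition(self):
        """Trials entering the 'item' condition of the encoding model
        (item memory with or without an incorrect source judgement)."""
        return self.n_item + self.n_incorrect_source


def score_subject(trials):
    """Score one subject's old-item trials.

    ``trials`` is a DataFrame with columns ``is_old, q1, q2, q3``; new-item
    rows, if present, are ignored.
    """
    old = trials[trials["is_old"].astype(bool)]
    if len(old) == 0:
        raise ValueError("no old trials to score")
    counts = {c: 0 for c in CATEGORIES}
    for row in old.itertuples(index=False):
        counts[classify_trial(True, row.q1, row.q2, row.q3)] += 1
    return MemoryScore(
        n_source=counts["source"], n_item=counts["item"],
        n_incorrect_source=counts["incorrect_source"], n_miss=counts["miss"],
        n_no_response=counts["no_response"], n_old=len(old),
    )


def score_all(trials):
    """Score every subject in a long trial table; returns one row each."""
    rows = []
    for s_id, grp in trials.groupby("subject_id", sort=True):
        ms = score_subject(grp)
        rows.append({
            "subject_id": s_id, "n_source": ms.n_source, "n_item": ms.n_item,
            "n_incorrect_source": ms.n_incorrect_source, "n_miss": ms.n_miss,
            "n_no_response": ms.n_no_response, "n_old": ms.n_old,
            "corrected_index": ms.corrected_index,
        })
    return pd.DataFrame(rows)


def exclude_low_trial_subjects(scores, min_trials=6):
    """Split subjects into kept/excluded by per-condition trial counts.

    A subject is excluded when either condition entering the encoding model
    has fewer than ``min_trials`` trials: the source condition
    (``n_source``) or the item condition (``n_item + n_incorrect_source``).
    Returns ``(kept_ids, excluded_ids)`` as lists.
    """
    if min_trials < 0:
        raise ValueError("min_trials must be nonnegative")
    n_item_cond = scores["n_item"] + scores["n_incorrect_source"]
    bad = (scores["n_source"] < min_trials) | (n_item_cond < min_trials)
    kept = scores.loc[~bad, "subject_id"].tolist()
    excluded = scores.loc[bad, "subject_id"].tolist()
    return kept, excluded
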