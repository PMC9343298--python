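"""False-negative outcome audit.

A false negative is a comatose patient the classifier labels as control.
The audit relates those misclassifications to the known 3-month outcome:
the FN good-outcome rate is the percentage of false negatives with a
favorable outcome (minimally conscious state) over all false negatives
of that MR index.  A high rate supports the hypothesis that patients on
a recovery trajectory already share imaging traits with controls.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import ValidationError
from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL


def fn_good_outcome_rate(good_outcome_fn: int, total_fn: int) -> int:
    """Round-half-up integer percentage of false negatives with favorable
    outcome.  ``total_fn == 0`` raises: the rate is undefined (reported
    as missing upstream for indices without false negatives)."""
    if total_fn < 1:
        raise ValidationError("rate undefined: no false negatives")
    if not 0 <= good_outcome_fn <= total_fn:
        raise ValidationError("good-outcome count outside [0, total]")
    return (200 * good_outcome_fn + total_fn) // (2 * total_fn)


def audit_table(per_index_labels: pd.DataFrame, true_labels: pd.Series,
                outcomes: pd.Series) -> pd.DataFrame:
    """One row per MR index (plus the majority-vote column if present).

    ``per_index_labels``: subjects x indices per-subject predicted
    labels; ``true_labels``/``outcomes`` aligned on subject id (outcome
    may be missing for controls, never for a patient counted as FN).
    Columns: index, good_outcome_fn, total_fn, rate_percent (missing
    when there is no FN).
    """
    rows = []
    for index_name in per_index_labels.columns:
        preds = per_index_labels[index_name]
        fn_ids = [sid for sid in preds.index
                  if true_labels.loc[sid] == POSITIVE_LABEL
                  and preds.loc[sid] == NEGATIVE_LABEL]
        total = len(fn_ids)
        if total:
            missing = [sid for sid in fn_ids if pd.isna(outcomes.loc[sid])]
            if missing:
                raise ValidationError(f"missing outcome for false negatives {missing}")
            good = sum(outcomes.loc[sid] == "favorable" for sid in fn_ids)
            rate: float | None = fn_good_outcome_rate(good, total)
        else:
            good, rate = 0, None
        rows.append({"index": index_name, "good_outcome_fn": good,
                     "total_fn": total, "rate_percent": rate})
    return pd.DataFrame(rows)


def fn_listing(per_index_labels: pd.DataFrame, true_labels: pd.Series,
               outcomes: pd.Series) -> pd.DataFrame:
    """Per-FN subject listing: subject_id, index, outcome."""
    rows = []
    for index_name in per_index_labels.columns:
        preds = per_index_labels[index_name]
        for sid in preds.index:
            if true_labels.loc[sid] == POSITIVE_LABEL and preds.loc[sid] == NEGATIVE_LABEL:
                rows.append({"subject_id": sid, "index": index_name,
                             "outcome": outcomes.loc[sid]})
    return pd.DataFrame(rows, columns=["subject_id", "index", "outcome"])
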