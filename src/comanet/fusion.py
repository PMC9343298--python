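"""Majority-vote fusion of the six per-index predictions per subject.

The fused label is the modal per-index prediction.  With six voters a
3-3 tie is possible; it falls back to the mean positive-class
probability across indices (>= 0.5 predicts coma) and is flagged so the
fallback remains auditable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .metrics import NEGATIVE_LABEL, POSITIVE_LABEL, confusion_counts


def majority_vote(per_index_labels, per_index_probabilities=None,
                  positive: str = POSITIVE_LABEL):
    """(fused label, tie flag) from one subject's per-index predictions."""
    labels = list(per_index_labels)
    if len(labels) < 2:
        raise ValidationError("majority voting needs at least two index predictions")
    n_pos = sum(1 for lab in labels if lab == positive)
    n_neg = len(labels) - n_pos
    if n_pos > n_neg:
        return positive, False
    if n_neg > n_pos:
        return NEGATIVE_LABEL, False
    if per_index_probabilities is None:
        raise ValidationError("tied vote requires per-index probabilities to resolve")
    mean_p = float(np.mean(list(per_index_probabilities)))
    return (positive if mean_p >= 0.5 else NEGATIVE_LABEL), True


def voting_report(per_index_labels: pd.DataFrame,
                  per_index_probs: pd.DataFrame | None,
                  true_labels: pd.Series):
    """Per-subject table (indices + fused vote) and fused confusion counts.

    ``per_index_labels``: subjects x MR indices, one predicted label per
    cell; ``true_labels`` aligned on the same subject index.  Returns
    ``(table, (tp, fp, tn, fn))``.
    """
    if per_index_labels.index.duplicated().any():
        raise ValidationError("duplicate subject ids in the voting table")
    fused, ties = [], []
    for sid, row in per_index_labels.iterrows():
        probs = per_index_probs.loc[sid] if per_index_probs is not None else None
        label, tie = majority_vote(row.to_list(),
                                   None if probs is None else probs.to_list())
        fused.append(label)
        ties.append(tie)
    table = per_index_labels.copy()
    table["MajVot"] = fused
    table["tie"] = ties
    table["true_label"] = true_labels.loc[table.index].to_numpy()
    counts = confusion_counts(table["true_label"], table["MajVot"])
    return table, counts
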