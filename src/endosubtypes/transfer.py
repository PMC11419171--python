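"""Cluster-label transfer to genotyped cohorts by K-nearest neighbors.

The derivation cohort's feature matrix and final cluster labels form the
training set; endometriosis cases in each genotyped cohort are assigned
the majority label of their k=3 nearest training subjects under
Manhattan distance (on binary features this is the Hamming count).

Exact distance ties are common on binary vectors, so the tie rules are
explicit and deterministic:

* neighbor-boundary ties: every training point tied with the k-th
  nearest distance is included in the vote;
* vote ties: the label of the single nearest neighbor among the tied
  labels wins (nearest = smallest distance, then smallest training
  index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import PhenotypeMatrix

__all__ = ["TransferModel", "knn_assign"]


@dataclass
class TransferModel:
    training: PhenotypeMatrix
    labels: np.ndarray
    k: int = 3
    metric: str = "cityblock"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.labels) != self.training.n_subjects:
            raise ValueError("training labels length mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Auditable flat view: features + assigned label per training row."""
        df = self.training.to_frame()
        df["cluster"] = self.labels
        return df


def knn_assign(model: TransferModel, test_X: PhenotypeMatrix) -> pd.DataFrame:
    """Assign each test subject the majority label of its k nearest
    training subjects.

    Returns a frame (subject_id, cluster, n_votes, mean_neighbor_distance)
    in test order. Feature columns must match the training matrix by name
    and order; a mismatch raises listing the unmatched columns.
    """
    if list(test_X.feature_names) != list(model.training.feature_names):
        train_set = set(model.training.feature_names)
        test_set = set(test_X.feature_names)
        unmatched = sorted(train_set ^ test_set)
        if unmatched:
            raise ValueError(f"feature mismatch between training and test: {unmatched}")
        raise ValueError("feature columns match by name but not order; reorder test matrix")
    D = cdist(np.asarray(test_X.values, float),
              np.asarray(model.training.values, float), metric=model.metric)
    n_train = model.training.n_subjects
    k = min(model.k, n_train)
    labels_out = np.empty(test_X.n_subjects, dtype=model.labels.dtype)
    votes_out = np.empty(test_X.n_subjects, dtype=int)
    meand_out = np.empty(test_X.n_subjects, dtype=float)
    for i in range(test_X.n_subjects):
        d = D[i]
        order = np.lexsort((np.arange(n_train), d))  # distance, then index
        kth = d[order[k - 1]]
        included = order[d[order] <= kth]  # all boundary ties included
        votes: dict = {}
        for j in included:
            votes[model.labels[j]] = votes.get(model.labels[j], 0) + 1
        top = max(votes.values())
        tied = [lab for lab, v in votes.items() if v == top]
        if len(tied) == 1:
            win = tied[0]
        else:
            # tie-break: single nearest neighbor among the tied labels
            for j in included:
                if model.labels[j] in tied:
                    win = model.labels[j]
                    break
        labels_out[i] = win
        votes_out[i] = votes[win]
        meand_out[i] = d[included].mean()
    return pd.DataFrame(
        {
            "subject_id": test_X.subject_ids,
            "cluster": labels_out,
            "n_votes": votes_out,
            "mean_neighbor_distance": meand_out,
        }
    )
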