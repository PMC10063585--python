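"""Label propagation: agreement-based strong labeling and the
nearest-to-centroid (KNN) label update.

The evolving partition of the dataset into labeled (S_l) and unlabeled
(S_u) samples lives in a :class:`PropagationState`. Two promotion
mechanisms act on it each outer iteration:

* **agreement** — an unlabeled sample whose classifier label L1 equals
  its (class-aligned) spectral cluster label L2 becomes strong-labeled
  with that agreed label;
* **knn** — within each cluster, the S unlabeled members nearest to the
  centroid of the cluster's labeled members (in embedding space) are
  promoted with the cluster's aligned class label.

Promoted samples are never demoted or relabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datasets import DataValidationError

SOURCE_INITIAL = "initial"
SOURCE_AGREEMENT = "agreement"
SOURCE_KNN = "knn"
SOURCE_FALLBACK = "fallback"


@dataclass
class PropagationState:
    """Working labels, supervision flags and per-iteration history.

    ``working`` holds the current label of every sample (-1 while
    unlabeled); ``source`` records how each label was obtained and
    ``promoted_at`` the outer iteration of promotion (0 = initial).
    """

    working: np.ndarray
    source: np.ndarray
    promoted_at: np.ndarray
    n_classes: int
    iteration: int = 0
    L1: np.ndarray | None = None          # classifier labels, all samples
    confidence: np.ndarray | None = None
    L2: np.ndarray | None = None          # cluster ids, all samples
    alignment: dict[int, int] | None = None
    history: list[dict] = field(default_factory=list)

    @classmethod
    def from_dataset(cls, dataset, n_classes: int | None = None
                     ) -> "PropagationState":
        n = len(dataset)
        working = np.where(dataset.labeled, dataset.y, -1).astype(np.int64)
        source = np.array([SOURCE_INITIAL if l else "" for l in dataset.labeled],
                          dtype=object)
        return cls(working=working, source=source,
                   promoted_at=np.where(dataset.labeled, 0, -1),
                   n_classes=n_classes or dataset.n_classes)

    # -- partition views ---------------------------------------------------
    @property
    def labeled_mask(self) -> np.ndarray:
        return self.working >= 0

    @property
    def S_l(self) -> np.ndarray:
        return np.flatnonzero(self.labeled_mask)

    @property
    def S_u(self) -> np.ndarray:
        return np.flatnonzero(~self.labeled_mask)

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())

    def aligned_L2(self) -> np.ndarray:
        """Cluster labels mapped onto class ids via the alignment map."""
        if self.L2 is None or self.alignment is None:
            raise DataValidationError("cluster labels or alignment missing")
        return np.array([self.alignment[int(c)] for c in self.L2])

    def promote(self, ids: np.ndarray, labels: np.ndarray, source: str) -> None:
        ids = np.asarray(ids, dtype=np.int64)
        if ids.size == 0:
            return
        if np.any(self.working[ids] >= 0):
            raise DataValidationError("cannot promote an already labeled sample")
        self.working[ids] = labels
        self.source[ids] = source
        self.promoted_at[ids] = self.iteration

    def record(self, **counts) -> None:
        self.history.append({
            "iteration": self.iteration,
            "n_labeled": self.n_labeled,
            "n_unlabeled": len(self.working) - self.n_labeled,
            **counts,
        })


def align_clusters_to_classes(L2: np.ndarray, working: np.ndarray,
                              n_classes: int) -> dict[int, int]:
    """Maximum-agreement one-to-one map from cluster ids to class ids.

    Solved on the labeled contingency table (clusters x classes) by
    linear assignment; clusters with no labeled members take the unused
    class id with lowest index, and ties break toward lower class ids.
    The method assumes one cluster per subtype, so the number of distinct
    cluster ids must equal ``n_classes``.
    """
    L2 = np.asarray(L2, dtype=np.int64)
    k = int(L2.max()) + 1
    if k != n_classes:
        raise DataValidationError(
            f"number of clusters ({k}) must equal number of classes "
            f"({n_classes})")
    labeled = working >= 0
    table = np.zeros((k, n_classes), dtype=np.float64)
    np.add.at(table, (L2[labeled], working[labeled]), 1)
    tie = np.outer(k - np.arange(k), k - np.arange(k)) / (k ** 4 + 1.0)
    rows, cols = linear_sum_assignment(table + tie, maximize=True)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def agreement_update(state: PropagationState) -> np.ndarray:
    """Promote every unlabeled sample whose weak labels agree (L1 == L2).

    Returns the promoted sample indices (Delta-S).
    """
    if state.L1 is None:
        raise DataValidationError("classifier labels L1 missing")
    aligned = state.aligned_L2()
    unlabeled = state.S_u
    agree = unlabeled[state.L1[unlabeled] == aligned[unlabeled]]
    state.promote(agree, state.L1[agree], SOURCE_AGREEMENT)
    return agree


def knn_label_update(state: PropagationState, embeddings: np.ndarray,
                     S: int) -> np.ndarray:
    """Per cluster, promote the S unlabeled members nearest to the labeled
    centroid, with the cluster's aligned class label.

    Clusters with no labeled member (or no unlabeled members) are
    skipped; at most S * k samples are promoted per call. Distance ties
    break toward the lower sample index.
    """
    if state.L2 is None or state.alignment is None:
        raise DataValidationError("cluster labels or alignment missing")
    F = np.asarray(embeddings, dtype=np.float64)
    promoted = []
    labels = []
    labeled = state.labeled_mask
    for c in sorted(state.alignment):
        members = state.L2 == c
        lab_members = np.flatnonzero(members & labeled)
        unlab_members = np.flatnonzero(members & ~labeled)
        if lab_members.size == 0 or unlab_members.size == 0:
            continue
        centroid = F[lab_members].mean(axis=0)
        dist = np.linalg.norm(F[unlab_members] - centroid, axis=1)
        order = np.lexsort((unlab_members, dist))
        take = unlab_members[order[: min(S, unlab_members.size)]]
        promoted.append(take)
        labels.append(np.full(take.size, state.alignment[c]))
    if not promoted:
        return np.array([], dtype=np.int64)
    promoted = np.concatenate(promoted)
    state.promote(promoted, np.concatenate(labels), SOURCE_KNN)
    return promoted


def confidence_fallback(state: PropagationState) -> np.ndarray:
    """Stall fallback: promote the single most confident unlabeled sample
    per class, using the classifier's label."""
    if state.L1 is None or state.confidence is None:
        raise DataValidationError("classifier output missing")
    promoted = []
    for cls in range(state.n_classes):
        cand = state.S_u
        cand = cand[state.L1[cand] == cls]
        if cand.size == 0:
            continue
        best = cand[np.lexsort((cand, -state.confidence[cand]))[0]]
        promoted.append(best)
    promoted = np.array(promoted, dtype=np.int64)
    if promoted.size:
        state.promote(promoted, state.L1[promoted], SOURCE_FALLBACK)
    return promoted
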