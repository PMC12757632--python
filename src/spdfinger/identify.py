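"""1-nearest-neighbor connectome fingerprinting and its accuracy bookkeeping.

Identification treats each of the N subjects as a class.  Given the
cross-session distance table D[i, j] between train-session FC i and
test-session FC j:

* direction A (train as database): test FC j is labeled
  argmin_i D[i, j]; accuracy_A = correct / N;
* direction B (test as database): train FC i is labeled
  argmin_j D[i, j]; accuracy_B = correct / N;
* the identification rate is the mean of the two accuracies.

Argmin ties are broken by the lowest index, deterministically.  Matching a
subject to itself across sessions is the success criterion, so there is no
self-match exclusion: rows and columns are different scanning sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .connectome import Cohort
from .metrics import DivergenceMatrix, MetricSpec, pairwise_matrix

__all__ = ["IDResult", "nn_predict", "id_rate", "identify_cohort"]


@dataclass
class IDResult:
    """Outcome of one identification run."""

    id_rate: float
    accuracy_A: float
    accuracy_B: float
    predictions_A: np.ndarray
    predictions_B: np.ndarray
    correct_A: np.ndarray
    correct_B: np.ndarray
    spec: MetricSpec
    n_subjects: int
    subject_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "id_rate": self.id_rate,
            "accuracy_A": self.accuracy_A,
            "accuracy_B": self.accuracy_B,
            "n_subjects": self.n_subjects,
            "predictions": {
                "train_as_db": self.predictions_A.tolist(),
                "test_as_db": self.predictions_B.tolist(),
            },
        }
        d.update(self.spec.to_dict())
        if self.subject_ids:
            d["subject_ids"] = self.subject_ids
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def nn_predict(D: DivergenceMatrix | np.ndarray, direction: str) -> np.ndarray:
    """1-NN predictions from a distance table.

    ``train_as_db``: one prediction per test column (argmin over rows);
    ``test_as_db``: one prediction per train row (argmin over columns).
    np.argmin already breaks ties at the lowest index.
    """
    values = D.values if isinstance(D, DivergenceMatrix) else np.asarray(D, dtype=float)
    if values.size == 0:
        raise ValueError("empty distance table")
    if not np.all(np.isfinite(values)):
        raise ValueError("distance table contains non-finite entries")
    if direction == "train_as_db":
        return np.argmin(values, axis=0)
    if direction == "test_as_db":
        return np.argmin(values, axis=1)
    raise ValueError(f"direction must be 'train_as_db' or 'test_as_db', got {direction!r}")


def id_rate(D: DivergenceMatrix | np.ndarray) -> IDResult:
    """Both-direction 1-NN identification rate from an aligned square table.

    Row i and column i must be the same subject's two sessions.  The rate is
    exactly (accuracy_A + accuracy_B) / 2 of the stored per-direction
    accuracies.
    """
    if isinstance(D, DivergenceMatrix):
        values = D.values
        spec = D.spec
        subject_ids = list(D.train_ids)
        if list(D.train_ids) != list(D.test_ids):
            raise ValueError(
                "id_rate needs aligned subject ids: train and test orders differ"
            )
    else:
        values = np.asarray(D, dtype=float)
        spec = MetricSpec("alpha_z")
        subject_ids = []
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"distance table must be square, got {values.shape}")
    n = values.shape[0]
    pred_A = nn_predict(values, "train_as_db")
    pred_B = nn_predict(values, "test_as_db")
    idx = np.arange(n)
    correct_A = pred_A == idx
    correct_B = pred_B == idx
    acc_A = int(correct_A.sum()) / n
    acc_B = int(correct_B.sum()) / n
    return IDResult(
        id_rate=(acc_A + acc_B) / 2,
        accuracy_A=acc_A,
        accuracy_B=acc_B,
        predictions_A=pred_A,
        predictions_B=pred_B,
        correct_A=correct_A,
        correct_B=correct_B,
        spec=spec,
        n_subjects=n,
        subject_ids=subject_ids,
    )


def identify_cohort(cohort: Cohort, spec: MetricSpec) -> IDResult:
    """Run the full fingerprinting pipeline on a two-session cohort.

    Time-series cohorts are converted to connectomes first; session 1 forms
    the train set and session 2 the test set, in subject-id order.
    """
    fcs = cohort.to_connectomes()
    ids = fcs.subject_ids
    train = [fc.values for fc in fcs.sessions(0)]
    test = [fc.values for fc in fcs.sessions(1)]
    D = pairwise_matrix(train, test, spec, train_ids=ids, test_ids=ids)
    return id_rate(D)
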