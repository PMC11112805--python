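from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from symptomnet.network import SymptomNetwork
from symptomnet.scale import ITEM_KEYS, KEDS, CohortTable, TimepointMatrix


def make_cohort_frame(records: list[dict]) -> pd.DataFrame:
    """Wide cohort frame from dicts with subject_id, timepoint and item scores."""
    rows = []
    for rec in records:
        row = {"subject_id": rec["subject_id"], "timepoint": rec["timepoint"]}
        scores = rec.get("scores", [3] * 9)
        for key, s in zip(ITEM_KEYS, scores):
            row[key] = s
        rows.append(row)
    return pd.DataFrame(rows)


def constant_cohort(n: int = 10, score: int = 3,
                    timepoints: tuple[str, ...] = ("assessment",)) -> CohortTable:
    records = [
        {"subject_id": f"S{i:03d}", "timepoint": tp, "scores": [score] * 9}
        for tp in timepoints
        for i in range(n)
    ]
    return CohortTable(data=make_cohort_frame(records))


def matrix_from_array(x: np.ndarray, timepoint: str = "assessment") -> TimepointMatrix:
    x = np.asarray(x)
    return TimepointMatrix(
        values=x,
        subject_ids=np.array([f"S{i:05d}" for i in range(x.shape[0])]),
        timepoint=timepoint,
        scale=KEDS,
    )


def network_from_weights(w: np.ndarray, labels: tuple[str, ...] | None = None,
                         n: int | str = 100) -> SymptomNetwork:
    w = np.asarray(w, dtype=float)
    labels = labels or tuple(chr(ord("A") + i) for i in range(w.shape[0]))
    return SymptomNetwork(node_labels=labels, weights=w, n=n)


def random_pd_correlation(rng: np.random.Generator, k: int) -> np.ndarray:
    """Random well-conditioned correlation matrix via a random factor model."""
    a = rng.standard_normal((k, k + 3))
    cov = a @ a.T + 0.5 * np.eye(k)
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    return (r + r.T) / 2.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240523)
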