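"""Responder classification and score-matched group construction.

A subject responds to treatment (clinically significant change) when the
total score drops from baseline to follow-up by at least the scale's
reliable-change constant (9 points) AND the follow-up total falls
strictly below the risk cutoff (19).  Subjects without a follow-up total
are unclassified; subjects without a baseline total are dropped.

To compare responder and non-responder networks without confounding by
initial severity, groups are matched exactly on the integer baseline
total: within each baseline-total stratum, min(n_responder,
n_non_responder) subjects are kept per group, with the kept subset drawn
uniformly at random from the larger side.  Matched groups therefore have
identical baseline total-score multisets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scale import CohortTable, total_scores

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNCLASSIFIED = "unclassified"


class EmptyMatchError(ValueError):
    """No baseline-total stratum contains both responders and non-responders."""


@dataclass
class MatchResult:
    """Outcome of exact baseline-total matching."""

    matched: pd.DataFrame = field(repr=False)  # subject_id, group, stratum
    excluded: pd.DataFrame = field(repr=False)
    strata: pd.DataFrame = field(repr=False)  # stratum bookkeeping
    seed: int | None = None

    @property
    def n_per_group(self) -> int:
        return int((self.matched["group"] == RESPONDER).sum())

    def ids(self, group: str) -> np.ndarray:
        return self.matched.loc[self.matched["group"] == group, "subject_id"].to_numpy()


def classify_responders(
    cohort: CohortTable,
    baseline: str = "assessment",
    followup: str = "followup12m",
) -> pd.DataFrame:
    """Label each subject with a baseline total as responder/non-responder.

    Returns columns ``subject_id, baseline_total, followup_total, delta,
    label``.  Classification is deterministic and seed-free.
    """
    scale = cohort.scale
    base = total_scores(cohort, baseline)
    fup = total_scores(cohort, followup)

    n_no_baseline = cohort.n_subjects - base.notna().sum()
    if n_no_baseline:
        logger.warning("dropping %d subjects without a baseline total", n_no_baseline)

    base = base[base.notna()]
    fup = fup.reindex(base.index)
    delta = base - fup

    label = np.where(
        fup.isna(),
        UNCLASSIFIED,
        np.where(
            (delta >= scale.reliable_change) & (fup < scale.risk_cutoff),
            RESPONDER,
            NON_RESPONDER,
        ),
    )
    return pd.DataFrame(
        {
            "subject_id": base.index,
            "baseline_total": base.values,
            "followup_total": fup.values,
            "delta": delta.values,
            "label": label,
        }
    ).reset_index(drop=True)


def match_on_total(labels: pd.DataFrame, seed: int | None = None) -> MatchResult:
    """Exact stratified matching of responders to non-responders.

    ``labels`` is the output of :func:`classify_responders`; unclassified
    subjects are ignored.  Within each integer baseline-total stratum the
    larger group is randomly thinned to the size of the smaller one.
    Matched group sizes are seed-invariant; only which subjects of the
    larger side are excluded varies with the seed.
    """
    rng = np.random.default_rng(seed)
    classified = labels[labels["label"].isin([RESPONDER, NON_RESPONDER])]
    if classified.empty or classified["label"].nunique() < 2:
        raise EmptyMatchError("need non-empty responder and non-responder groups")

    matched_rows = []
    excluded_rows = []
    strata_rows = []
    for stratum, group in classified.groupby("baseline_total", sort=True):
        resp = group[group["label"] == RESPONDER]["subject_id"].to_numpy()
        nonr = group[group["label"] == NON_RESPONDER]["subject_id"].to_numpy()
        keep = min(len(resp), len(nonr))
        strata_rows.append(
            {
                "stratum": stratum,
                "n_responder": len(resp),
                "n_non_responder": len(nonr),
                "n_kept_per_group": keep,
            }
        )
        for ids, grp in ((resp, RESPONDER), (nonr, NON_RESPONDER)):
            if keep and len(ids) > keep:
                kept = rng.choice(ids, size=keep, replace=False)
            elif keep:
                kept = ids
            else:
                kept = np.array([], dtype=ids.dtype)
            kept_set = set(kept)
            for sid in ids:
                row = {"subject_id": sid, "group": grp, "stratum": stratum}
                (matched_rows if sid in kept_set else excluded_rows).append(row)

    if not matched_rows:
        raise EmptyMatchError("no overlapping baseline-total strata")
    matched = pd.DataFrame(matched_rows)
    excluded = pd.DataFrame(excluded_rows, columns=["subject_id", "group", "stratum"])
    return MatchResult(
        matched=matched, excluded=excluded, strata=pd.DataFrame(strata_rows), seed=seed
    )
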