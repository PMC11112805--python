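"""Permutation Network Comparison Test (NCT).

Compares two symptom networks on three statistics:

- global strength: |S1 - S2|, the difference in connectivity (sum of
  absolute partial correlations),
- structure: max_ij |rho1_ij - rho2_ij|, the largest single edge
  difference,
- individual edges: |rho1_ij - rho2_ij| per edge, Holm-adjusted.

Null distributions come from random rearrangement of participants.  In
the independent design, group labels are permuted over the pooled rows
preserving group sizes; in the paired design each subject's two
condition records are swapped independently with probability 1/2.
P-values use the add-one convention p = (1 + #{perm >= observed}) / (B + 1),
so the smallest attainable p is 1/(B+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import connectivity, partial_from_correlation
from .scale import CohortTable, TimepointMatrix, complete_cases

logger = logging.getLogger(__name__)

#: Omnibus alpha used only to flag whether edge-level tests are gated.
EDGE_GATE_ALPHA = 0.05


class PairedAlignmentError(ValueError):
    """Paired design requires the same subjects in both conditions."""


@dataclass
class NCTResult:
    """Observed statistics and permutation p-values for a two-network test."""

    s1: float
    s2: float
    global_strength_stat: float
    global_strength_p: float
    structure_stat: float
    structure_p: float
    edge_table: pd.DataFrame = field(repr=False)
    B: int = 0
    design: str = "independent"
    seed: int | None = None
    edges_gated: bool = True  # True: omnibus not significant, edge tests exploratory


def _pcor(x: np.ndarray) -> np.ndarray:
    """Partial Spearman correlations of a complete-case score matrix."""
    ranks = stats.rankdata(x, axis=0)
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        raise ValueError("constant column in permuted sample")
    r = np.corrcoef(ranks, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    p, _ = partial_from_correlation(r)
    return p


def _stats_pair(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float, np.ndarray]:
    p1 = _pcor(x1)
    p2 = _pcor(x2)
    iu = np.triu_indices(p1.shape[0], k=1)
    diff = np.abs(p1 - p2)[iu]
    return connectivity(p1), connectivity(p2), diff


def _as_values(matrix: TimepointMatrix | np.ndarray) -> np.ndarray:
    if isinstance(matrix, TimepointMatrix):
        return np.asarray(matrix.values, dtype=float)
    return np.asarray(matrix, dtype=float)


def nct(group_a: TimepointMatrix | np.ndarray,
        group_b: TimepointMatrix | np.ndarray,
        design: str = "independent",
        B: int = 10_000,
        seed: int | None = None) -> NCTResult:
    """Permutation test of network differences between two groups.

    ``group_a``/``group_b`` are complete-case score matrices.  For the
    paired design they must hold the same subjects in the same order
    (checked when subject ids are available).  A permutation on which
    estimation fails is redrawn and logged.
    """
    if design not in {"independent", "paired"}:
        raise ValueError("design must be 'independent' or 'paired'")
    xa, xb = _as_values(group_a), _as_values(group_b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups must share the item set")
    if design == "paired":
        if xa.shape[0] != xb.shape[0]:
            raise PairedAlignmentError("paired design requires equal group sizes")
        if isinstance(group_a, TimepointMatrix) and isinstance(group_b, TimepointMatrix):
            if list(group_a.subject_ids) != list(group_b.subject_ids):
                raise PairedAlignmentError(
                    "paired design requires identically ordered subject ids"
                )

    rng = np.random.default_rng(seed)
    s1, s2, edge_diff = _stats_pair(xa, xb)
    obs_gs = abs(s1 - s2)
    obs_struct = edge_diff.max()

    n_edges = edge_diff.size
    gs_null = np.empty(B)
    struct_null = np.empty(B)
    edge_ge = np.zeros(n_edges)
    n1 = xa.shape[0]
    pooled = np.vstack([xa, xb])
    redrawn = 0
    b = 0
    while b < B:
        if design == "independent":
            perm = rng.permutation(pooled.shape[0])
            y1, y2 = pooled[perm[:n1]], pooled[perm[n1:]]
        else:
            swap = rng.random(n1) < 0.5
            y1 = np.where(swap[:, None], xb, xa)
            y2 = np.where(swap[:, None], xa, xb)
        try:
            t1, t2, diff = _stats_pair(y1, y2)
        except Exception:  # noqa: BLE001 - redraw degenerate permutations
            redrawn += 1
            if redrawn > max(10, 0.01 * B):
                raise RuntimeError("permutation failure rate exceeded 1%")
            continue
        gs_null[b] = abs(t1 - t2)
        struct_null[b] = diff.max()
        edge_ge += diff >= edge_diff
        b += 1
    if redrawn:
        logger.warning("redrew %d degenerate permutations", redrawn)

    gs_p = (1.0 + np.sum(gs_null >= obs_gs)) / (B + 1)
    struct_p = (1.0 + np.sum(struct_null >= obs_struct)) / (B + 1)
    edge_p = (1.0 + edge_ge) / (B + 1)
    edge_holm = holm_adjust(edge_p)

    if isinstance(group_a, TimepointMatrix):
        labels = group_a.scale.item_labels
    else:
        labels = tuple(f"item_{i}" for i in range(xa.shape[1]))
    iu = np.triu_indices(len(labels), k=1)
    edge_table = pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu[0]],
            "node_j": [labels[j] for j in iu[1]],
            "abs_diff": edge_diff,
            "p_raw": edge_p,
            "p_holm": edge_holm,
        }
    )
    return NCTResult(
        s1=s1,
        s2=s2,
        global_strength_stat=obs_gs,
        global_strength_p=float(gs_p),
        structure_stat=float(obs_struct),
        structure_p=float(struct_p),
        edge_table=edge_table,
        B=B,
        design=design,
        seed=seed,
        edges_gated=bool(struct_p >= EDGE_GATE_ALPHA),
    )


def paired_complete_cases(
    cohort: CohortTable, timepoint_a: str, timepoint_b: str
) -> tuple[TimepointMatrix, TimepointMatrix]:
    """Aligned complete-case matrices for subjects observed at both waves.

    This is the input for a paired (longitudinal) NCT: the same subjects,
    one record per condition, identical ordering.
    """
    a = complete_cases(cohort, timepoint_a)
    b = complete_cases(cohort, timepoint_b)
    common = [sid for sid in a.subject_ids if sid in set(b.subject_ids)]
    if not common:
        raise PairedAlignmentError(
            f"no subjects complete at both {timepoint_a!r} and {timepoint_b!r}"
        )
    idx_a = {sid: i for i, sid in enumerate(a.subject_ids)}
    idx_b = {sid: i for i, sid in enumerate(b.subject_ids)}
    rows_a = [idx_a[s] for s in common]
    rows_b = [idx_b[s] for s in common]
    make = lambda m, rows, tp: TimepointMatrix(  # noqa: E731
        values=np.asarray(m.values)[rows],
        subject_ids=np.asarray(common),
        timepoint=tp,
        scale=m.scale,
    )
    return make(a, rows_a, timepoint_a), make(b, rows_b, timepoint_b)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
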