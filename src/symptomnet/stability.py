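"""Bootstrap uncertainty and stability of network estimates.

Two resampling schemes:

- non-parametric edge bootstrap: resample subjects with replacement,
  re-estimate the network, and report percentile confidence intervals
  per edge;
- case-dropping bootstrap: subsample increasing fractions of subjects
  without replacement and correlate the subsample centralities with the
  full-sample centralities.  The correlation-stability (CS) coefficient
  is the largest drop proportion at which that correlation stays at or
  above r = 0.7 in at least 95% of subsamples; CS >= 0.5 is read as
  stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import INDICES, centrality_vectors
from .network import SymptomNetwork, edge_vector, estimate_network
from .scale import TimepointMatrix

logger = logging.getLogger(__name__)

#: Default case-dropping grid: 5% to 75% in 5% steps.
DEFAULT_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))

#: CS decision constants: required correlation, required subsample fraction,
#: and the conventional stability verdict threshold.
CS_R_MIN = 0.7
CS_PROB = 0.95
CS_STABLE = 0.5

MAX_FAILURE_FRACTION = 0.01


@dataclass
class EdgeBootstrapResult:
    """Per-edge sample estimate, bootstrap mean and percentile 95% CI."""

    table: pd.DataFrame = field(repr=False)
    B: int = 0
    seed: int | None = None
    n_redrawn: int = 0


@dataclass
class CSResult:
    """Case-dropping bootstrap correlations and CS coefficients."""

    quantiles: pd.DataFrame = field(repr=False)  # per index x proportion
    correlations: dict[str, np.ndarray] = field(repr=False)  # (grid, B_per)
    grid: tuple[float, ...] = ()
    B_per: int = 0
    seed: int | None = None


def _resampled_network(values: np.ndarray, rows: np.ndarray,
                       template: TimepointMatrix) -> SymptomNetwork:
    sub = TimepointMatrix(
        values=values[rows],
        subject_ids=template.subject_ids[rows],
        timepoint=template.timepoint,
        scale=template.scale,
    )
    return estimate_network(sub)


def bootstrap_edges(matrix: TimepointMatrix, B: int = 10_000,
                    seed: int | None = None,
                    levels: tuple[float, ...] = (0.025, 0.975)) -> EdgeBootstrapResult:
    """Non-parametric bootstrap CIs for all edge weights.

    Rows are resampled with replacement ``B`` times; a resample on which
    estimation fails (e.g. a constant column) is redrawn and counted, and
    more than 1% failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    sample_net = estimate_network(matrix)
    est = edge_vector(sample_net)
    n = matrix.n
    values = np.asarray(matrix.values)

    draws = np.empty((B, est.size))
    failures = 0
    b = 0
    while b < B:
        rows = rng.integers(0, n, size=n)
        try:
            net = _resampled_network(values, rows, matrix)
        except Exception:  # noqa: BLE001 - any estimation failure triggers redraw
            failures += 1
            if failures > max(10, MAX_FAILURE_FRACTION * B):
                raise RuntimeError(
                    f"bootstrap failure rate exceeded {MAX_FAILURE_FRACTION:.0%}"
                )
            continue
        draws[b] = edge_vector(net)
        b += 1
    if failures:
        logger.warning("redrew %d failed bootstrap resamples", failures)

    lo, hi = np.quantile(draws, levels, axis=0)
    labels = sample_net.node_labels
    iu = np.triu_indices(len(labels), k=1)
    table = pd.DataFrame(
        {
            "node_i": [labels[i] for i in iu[0]],
            "node_j": [labels[j] for j in iu[1]],
            "estimate": est,
            "boot_mean": draws.mean(axis=0),
            "lo95": lo,
            "hi95": hi,
        }
    )
    return EdgeBootstrapResult(table=table, B=B, seed=seed, n_redrawn=failures)


def case_drop_bootstrap(matrix: TimepointMatrix,
                        grid: tuple[float, ...] = DEFAULT_GRID,
                        B_per: int = 1_000,
                        seed: int | None = None,
                        min_rows: int = 20) -> CSResult:
    """Case-dropping bootstrap of the centrality indices.

    For each drop proportion p, draw ``B_per`` subsamples of
    ceil((1-p)*n) rows without replacement and record the Pearson
    correlation between subsample and full-sample raw centralities for
    each index.  A correlation that is undefined (constant centralities)
    or from a failed estimation counts as NaN and is treated as failing
    the r >= 0.7 criterion downstream.
    """
    grid = tuple(sorted(float(p) for p in grid))
    if not all(0 < p < 0.95 for p in grid):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    rng = np.random.default_rng(seed)
    n = matrix.n
    values = np.asarray(matrix.values)
    full = centrality_vectors(estimate_network(matrix))

    kept_grid: list[float] = []
    correlations: dict[str, list[np.ndarray]] = {idx: [] for idx in INDICES}
    for p in grid:
        m = int(np.ceil((1 - p) * n))
        if m < min_rows:
            logger.warning("skipping drop proportion %.2f: subset of %d rows", p, m)
            continue
        kept_grid.append(p)
        cors = {idx: np.full(B_per, np.nan) for idx in INDICES}
        for b in range(B_per):
            rows = rng.choice(n, size=m, replace=False)
            try:
                sub = centrality_vectors(_resampled_network(values, rows, matrix))
            except Exception:  # noqa: BLE001
                continue
            for idx in INDICES:
                cors[idx][b] = _safe_pearson(sub[idx], full[idx])
        for idx in INDICES:
            correlations[idx].append(cors[idx])

    qrows = []
    for idx in INDICES:
        for p, c in zip(kept_grid, correlations[idx]):
            finite = c[np.isfinite(c)]
            qrows.append(
                {
                    "index": idx,
                    "proportion": p,
                    "q025": np.quantile(finite, 0.025) if finite.size else np.nan,
                    "median": np.quantile(finite, 0.5) if finite.size else np.nan,
                    "q975": np.quantile(finite, 0.975) if finite.size else np.nan,
                    "frac_ge_rmin": float(np.mean(np.nan_to_num(c, nan=-2.0) >= CS_R_MIN)),
                }
            )
    return CSResult(
        quantiles=pd.DataFrame(qrows),
        correlations={idx: np.vstack(correlations[idx]) for idx in INDICES},
        grid=tuple(kept_grid),
        B_per=B_per,
        seed=seed,
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cs_coefficient(result: CSResult, r_min: float = CS_R_MIN,
                   prob: float = CS_PROB) -> pd.DataFrame:
    """CS coefficient per index with the conventional stability verdict.

    CS is the largest grid proportion p such that at every proportion up
    to and including p the fraction of subsamples correlating >= r_min
    with the full sample is >= prob (ties count as qualifying); 0 when no
    proportion qualifies.  The monotone-prefix scan keeps CS well defined
    even when the empirical fractions are not monotone in p.
    """
    if not result.grid:
        raise ValueError("empty CS result")
    rows = []
    for idx in INDICES:
        cors = result.correlations[idx]
        frac = np.mean(np.nan_to_num(cors, nan=-2.0) >= r_min, axis=1)
        cs = 0.0
        for p, q in zip(result.grid, frac):
            if q >= prob:
                cs = p
            else:
                break
        rows.append(
            {"index": idx, "cs": cs, "verdict": "stable" if cs >= CS_STABLE else "unstable"}
        )
    return pd.DataFrame(rows)
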