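"""Synthetic longitudinal ordinal cohorts with known network ground truth.

The generator emulates a treated exhaustion-disorder cohort measured
with a 9-item 0-6 scale at five waves: declining symptom means over
treatment, modest wave-on-wave attrition, and a latent improver class
that drives responder/non-responder heterogeneity at follow-up.

Data-generating model (latent Gaussian copula):

1.  A target partial-correlation matrix P among the nine latent item
    variables defines the precision matrix K (unit diagonal,
    K_ij = -P_ij); the latent correlation R is the standardized inverse
    of K, so the partial correlations of R equal P exactly.
2.  Subject s at wave t has latent vector
    (u_s + e_st) / sqrt(1 + sigma_u^2) + delta_t  where
    u_s ~ MVN(0, sigma_u^2 R) is a stable subject effect,
    e_st ~ MVN(0, R) is wave noise, and delta_t is the per-item wave
    shift.  Scaling keeps the marginal latent distribution N(delta_t, R)
    at every wave, so the cross-sectional correlation structure is R
    regardless of sigma_u.
3.  Latents are discretized through per-item ascending thresholds into
    scores 0-6.  Thresholds and wave shifts are calibrated numerically
    (closed-form normal arithmetic + root finding) so that the expected
    item means reproduce the default marginal targets.
4.  An improver class (default proportion 0.42) receives an extra
    negative latent offset at the 12-month follow-up; the follow-up wave
    shift is calibrated on the mixture, leaving marginal means intact.
5.  Attrition removes each subject's record at a wave independently
    (missing completely at random) with per-wave probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .network import SymptomNetwork
from .scale import ITEM_KEYS, KEDS, TIMEPOINTS, CohortTable, ScaleDefinition

N_ITEMS = len(ITEM_KEYS)
N_WAVES = len(TIMEPOINTS)

#: Default marginal calibration targets: per-item mean at each wave for a
#: large treated exhaustion-disorder cohort (rows = items in scale order,
#: columns = waves from initial assessment to 12-month follow-up).
DEFAULT_ITEM_MEANS = np.array(
    [
        [3.81, 3.64, 3.07, 2.49, 2.25],  # concentration
        [3.84, 3.59, 3.16, 2.79, 2.53],  # memory
        [3.38, 3.30, 2.79, 2.32, 2.14],  # physical stamina
        [3.94, 3.72, 3.03, 2.50, 2.28],  # mental stamina
        [4.52, 4.26, 3.49, 2.99, 2.74],  # recovery
        [3.95, 3.71, 2.93, 2.46, 2.34],  # sleep
        [3.93, 3.74, 3.17, 2.74, 2.51],  # sensory sensitivity
        [4.08, 3.80, 3.08, 2.47, 2.25],  # experience of demands
        [3.35, 3.09, 2.52, 1.96, 1.91],  # irritation/anger
    ]
)

#: Baseline item standard deviations used to set threshold spacing.
DEFAULT_ITEM_SDS = np.array([1.02, 1.28, 1.07, 0.89, 1.10, 1.44, 1.41, 0.88, 1.40])

#: Per-wave record attrition probabilities (missing completely at random).
DEFAULT_ATTRITION = (1 / 915, 9 / 915, 28 / 915, 49 / 915, 132 / 915)

_E = dict((k, i) for i, k in enumerate(ITEM_KEYS))


def _build_true_pcor() -> np.ndarray:
    """Planted partial-correlation structure.

    Qualitative motifs: memory-concentration and recovery-mental stamina
    are the strongest conditional associations; mental stamina and the
    experience of demands are hubs; sleep and irritation connect weakly.
    Row sums stay below 1 so the implied precision matrix is strictly
    diagonally dominant, hence positive definite.
    """
    edges = {
        ("memory", "concentration"): 0.33,
        ("recovery", "mental_stamina"): 0.30,
        ("mental_stamina", "experience_of_demands"): 0.22,
        ("sensory_sensitivity", "experience_of_demands"): 0.18,
        ("physical_stamina", "mental_stamina"): 0.18,
        ("concentration", "experience_of_demands"): 0.15,
        ("physical_stamina", "recovery"): 0.12,
        ("concentration", "mental_stamina"): 0.10,
        ("recovery", "experience_of_demands"): 0.10,
        ("memory", "sensory_sensitivity"): 0.08,
        ("recovery", "sleep"): 0.08,
        ("experience_of_demands", "irritation_anger"): 0.08,
        ("sleep", "sensory_sensitivity"): 0.07,
        ("mental_stamina", "sleep"): 0.06,
        ("sensory_sensitivity", "irritation_anger"): 0.06,
    }
    p = np.zeros((N_ITEMS, N_ITEMS))
    for (a, b), w in edges.items():
        p[_E[a], _E[b]] = p[_E[b], _E[a]] = w
    return p


DEFAULT_TRUE_PCOR = _build_true_pcor()


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Full data-generating specification for a synthetic cohort."""

    n_subjects: int = 915
    true_pcor: np.ndarray = field(default_factory=lambda: DEFAULT_TRUE_PCOR.copy())
    item_thresholds: np.ndarray | None = None  # (n_items, 6), ascending per row
    time_shifts: np.ndarray | None = None  # (n_waves, n_items) latent offsets
    subject_sd: float = 0.5
    responder_mix: tuple[float, float] = (0.42, -1.0)  # (proportion, follow-up offset)
    attrition_rates: tuple[float, ...] = DEFAULT_ATTRITION
    seed: int = 0
    scale: ScaleDefinition = field(default_factory=lambda: KEDS)
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        self.true_pcor = np.asarray(self.true_pcor, dtype=float)
        k = self.scale.n_items
        if self.true_pcor.shape != (k, k):
            raise ConfigError("true_pcor must be items x items")
        if not np.allclose(self.true_pcor, self.true_pcor.T):
            raise ConfigError("true_pcor must be symmetric")
        if not np.allclose(np.diag(self.true_pcor), 0.0):
            raise ConfigError("true_pcor diagonal must be zero")
        if np.abs(self.true_pcor).max(initial=0) >= 1:
            raise ConfigError("partial correlations must lie in (-1, 1)")
        vals = np.linalg.eigvalsh(self._precision())
        if vals.min() <= 0:
            raise ConfigError("implied precision matrix is not positive definite")
        prop, _ = self.responder_mix
        if not 0 <= prop <= 1:
            raise ConfigError("responder proportion must lie in [0, 1]")
        if len(self.attrition_rates) != len(self.timepoints):
            raise ConfigError("one attrition rate per timepoint required")
        if not all(0 <= a < 1 for a in self.attrition_rates):
            raise ConfigError("attrition rates must lie in [0, 1)")
        if self.item_thresholds is not None:
            self.item_thresholds = np.asarray(self.item_thresholds, dtype=float)
            if self.item_thresholds.shape != (k, self.scale.item_max):
                raise ConfigError("thresholds must be items x (item_max) ascending cuts")
            if not (np.diff(self.item_thresholds, axis=1) > 0).all():
                raise ConfigError("thresholds must be strictly ascending")
        if self.time_shifts is not None:
            self.time_shifts = np.asarray(self.time_shifts, dtype=float)
            if self.time_shifts.shape != (len(self.timepoints), k):
                raise ConfigError("time_shifts must be waves x items")

    def _precision(self) -> np.ndarray:
        k = np.eye(self.scale.n_items) - self.true_pcor
        return k

    def latent_correlation(self) -> np.ndarray:
        """Latent correlation matrix whose partial correlations equal true_pcor."""
        cov = np.linalg.inv(self._precision())
        d = np.sqrt(np.diag(cov))
        r = cov / np.outer(d, d)
        return (r + r.T) / 2.0


def _expected_score(thresholds: np.ndarray, shift: float) -> float:
    """E[score] for latent N(shift, 1) discretized at the given cuts."""
    return float(np.sum(1.0 - norm.cdf(thresholds - shift)))


def _solve_shift(thresholds: np.ndarray, target: float,
                 mix: tuple[float, float] | None = None) -> float:
    """Wave shift d with E[score] = target, optionally under an improver mixture."""

    def mean_at(d: float) -> float:
        if mix is None:
            return _expected_score(thresholds, d)
        prop, off = mix
        return prop * _expected_score(thresholds, d + off) + (1 - prop) * _expected_score(
            thresholds, d
        )

    return brentq(lambda d: mean_at(d) - target, -10.0, 10.0, xtol=1e-10)


def calibrate_marginals(
    item_means: np.ndarray = DEFAULT_ITEM_MEANS,
    item_sds: np.ndarray = DEFAULT_ITEM_SDS,
    responder_mix: tuple[float, float] = (0.42, -1.0),
    followup_wave: int = N_WAVES - 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Thresholds and wave shifts reproducing target item means.

    Thresholds are spaced as score-boundary quantiles of a normal with
    the item's baseline mean and SD, then anchored so the baseline shift
    is exactly zero; subsequent wave shifts are solved by root finding.
    The follow-up shift is solved on the improver mixture so that the
    marginal mean stays on target.
    """
    n_items, n_waves = item_means.shape
    max_score = 6
    thresholds = np.empty((n_items, max_score))
    shifts = np.zeros((n_waves, n_items))
    for j in range(n_items):
        cuts = (np.arange(1, max_score + 1) - 0.5 - item_means[j, 0]) / item_sds[j]
        # anchor: absorb the residual baseline shift into the thresholds
        d0 = _solve_shift(cuts, item_means[j, 0])
        thresholds[j] = cuts - d0
        for t in range(1, n_waves):
            mix = responder_mix if t == followup_wave else None
            shifts[t, j] = _solve_shift(thresholds[j], item_means[j, t], mix=mix)
    return thresholds, shifts


def default_config(seed: int = 0, n_subjects: int = 915) -> GeneratorConfig:
    """The default synthetic-cohort specification.

    n = 915 subjects over five waves with calibrated marginal decline,
    attrition of (1, 9, 28, 49, 132)/915 records per wave, the planted
    default network structure, and a 42% improver class.
    """
    thresholds, shifts = calibrate_marginals()
    return GeneratorConfig(
        n_subjects=n_subjects,
        item_thresholds=thresholds,
        time_shifts=shifts,
        seed=seed,
    )


def generate(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort from the generator; fully reproducible from the seed."""
    if config.item_thresholds is None or config.time_shifts is None:
        thresholds, shifts = calibrate_marginals(responder_mix=config.responder_mix)
    else:
        thresholds, shifts = config.item_thresholds, config.time_shifts

    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    k = config.scale.n_items
    r = config.latent_correlation()
    chol = np.linalg.cholesky(r)
    prop, offset = config.responder_mix

    improver = rng.random(n) < prop
    u = (rng.standard_normal((n, k)) @ chol.T) * config.subject_sd
    scale_factor = np.sqrt(1.0 + config.subject_sd**2)
    subject_ids = np.array([f"S{i:05d}" for i in range(n)])

    frames = []
    followup_wave = len(config.timepoints) - 1
    for t, tp in enumerate(config.timepoints):
        e = rng.standard_normal((n, k)) @ chol.T
        latent = (u + e) / scale_factor + shifts[t]
        if t == followup_wave:
            latent[improver] += offset
        scores = np.empty((n, k), dtype=np.int64)
        for j in range(k):
            scores[:, j] = np.searchsorted(thresholds[j], latent[:, j], side="left")
        dropped = rng.random(n) < config.attrition_rates[t]
        keep = ~dropped
        frame = pd.DataFrame(scores[keep], columns=list(config.scale.item_labels))
        frame.insert(0, "timepoint", tp)
        frame.insert(0, "subject_id", subject_ids[keep])
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    order = {s: i for i, s in enumerate(subject_ids)}
    data = data.sort_values(
        by=["subject_id", "timepoint"],
        key=lambda col: col.map(order)
        if col.name == "subject_id"
        else col.map({tp: i for i, tp in enumerate(config.timepoints)}),
        kind="stable",
    ).reset_index(drop=True)
    return CohortTable(data=data, scale=config.scale, timepoints=config.timepoints)


def true_network(config: GeneratorConfig) -> SymptomNetwork:
    """Ground-truth partial-correlation network of the generator."""
    return SymptomNetwork(
        node_labels=tuple(config.scale.item_labels),
        weights=config.true_pcor,
        n="population",
        timepoint=None,
    )
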