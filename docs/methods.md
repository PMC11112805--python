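# Methods

## Scale and data model

The default instrument is the KEDS: nine exhaustion-disorder symptoms
(concentration, memory, physical stamina, mental stamina, recovery,
sleep, sensory hypersensitivity, experience of demands,
irritation/anger), each rated 0–6, total 0–54.  Two clinical constants
live in the scale definition: the risk cutoff (total ≥ 19 indicates
"at risk") and the reliable-change threshold (a drop of ≥ 9 points).
Both are configuration, so other ordinal scales can be analyzed by
supplying a different `ScaleDefinition`.

A cohort is a long table of (subject, wave) records over the five study
waves (assessment, treatment start, midpoint, end, 12-month follow-up);
any ordered subset of waves is accepted since all network analyses are
per wave.  Analyses are complete-case per wave: a record with any
missing item is excluded from that wave's matrix, and a total score
with any missing item is treated as missing rather than prorated —
prorating would be inconsistent with complete-case estimation.
Summary percentages are rounded half-up to integers for display.

## Network estimation

Spearman correlations are computed as Pearson correlations of
column-wise average ranks (ties get average ranks); partial
correlations follow from the precision matrix,
`ρ_ij = −K_ij/√(K_ii K_jj)`, `K = R⁻¹`.  No regularization is applied —
with n in the hundreds and 9 nodes, unregularized estimates are stable
and unbiased by shrinkage.

Degenerate inputs are handled explicitly rather than silently:

- a constant item column raises an error naming the item;
- if the smallest eigenvalue of `R` falls below 1e−8 (possible in small
  bootstrap subsamples), `R` is projected to the nearest positive
  definite correlation matrix by eigenvalue clipping at 1e−8 plus
  re-standardization; the repair is logged and recorded on the network
  object (`pd_repaired`);
- partials are clamped to [−1, 1] with a warning; clamping cannot occur
  on positive definite inputs and the tests assert it does not.

Connectivity (global strength) is `S = Σ_{i<j} |ρ_ij|`.  Edge signs are
kept; absolute values feed connectivity, strength and distances.  The
display threshold (hide |ρ| < 0.1, strictly below) and the saturation
reference for figures are presentation parameters only and never enter
any statistic; the saturation reference defaults to the maximum |ρ|
observed across the networks of a run.

## Centrality

Distances are reciprocal absolute weights, `d_ij = 1/|ρ_ij|`, absent
edges are non-adjacent, shortest paths by Dijkstra.  Strength is the
absolute incident weight sum; closeness is `(k−1)/Σ_j d_ij`, set to 0
for any node with an unreachable partner (logged — only bootstrap
subsamples ever disconnect); betweenness is fractional Brandes counting
with unordered pairs counted once, the convention of the centrality
literature (a literal "number of times on the shortest path" is
ambiguous under ties).  z-standardization is per index across the nine
nodes with the n−1 SD; a constant raw column yields an all-zero
z-column by convention.  Since closeness normalizations differ only by
a monotone factor, the `(k−1)/Σd` choice affects no ordering or z
profile.

## Stability

Edge uncertainty: non-parametric bootstrap over subjects (default
B = 10,000 when run at study scale; analysis drivers default lower for
desk runs), percentile 2.5/97.5 intervals per edge.  A resample on
which estimation fails is redrawn and counted; more than 1% failures
aborts.

Centrality stability: case-dropping bootstrap over a grid of drop
proportions (default 0.05–0.75 by 0.05, B_per = 1,000 default), Pearson
correlation of raw (not z) subsample centralities with full-sample
centralities.  An undefined correlation (constant centralities or a
failed subsample) counts as failing the criterion.  The CS coefficient
is the largest grid proportion p such that every proportion ≤ p has at
least 95% of subsamples with r ≥ 0.7 (ties qualify); the prefix scan
keeps CS well defined when empirical fractions are non-monotone.  The
conventional verdict threshold is CS ≥ 0.5.  Per-proportion bootstrap
quantiles (2.5/50/97.5%) of the correlations are reported; no interval
is attached to the CS scalar itself, whose sampling distribution is a
step function of the grid.

## Network comparison

The permutation test compares two networks on |S₁−S₂| (global
strength), max|Δρ| (structure) and per-edge |Δρ| (Holm-adjusted via
statsmodels).  Independent design: group labels permuted over pooled
rows preserving sizes.  Paired design: each subject's two condition
records are swapped independently with probability ½ — used for
longitudinal comparisons restricted to subjects complete at both waves,
since the same individuals are measured twice (the independent mode
remains available for sensitivity analysis).  P-values use the add-one
convention `(1 + #{perm ≥ obs})/(B + 1)`, so p ∈ [1/(B+1), 1] and a
zero p-value is impossible.  Per-edge tests are always reported; a flag
records whether the structure omnibus was non-significant so edge-level
findings should be read as exploratory.

## Responder classification and matching

Responder: drop from baseline to follow-up ≥ reliable change AND
follow-up total strictly below the risk cutoff (consistent with "19 or
above = at risk").  Missing follow-up → unclassified; missing baseline
→ dropped with a warning.  Matching is exact on integer baseline
totals — within each total-score stratum the larger group is thinned
uniformly at random to the smaller group's size — because the design
goal is *identical* baseline score distributions, which caliper or
nearest-neighbour matching would not guarantee.  Matched sizes are
seed-invariant; only which subjects are excluded varies.

## Synthetic cohort generator

The generator provides ground truth that real data cannot: a known
partial-correlation structure.

- **Latent structure.**  The planted partial-correlation matrix has
  row sums < 1, so the implied precision (unit diagonal, −ρ
  off-diagonal) is strictly diagonally dominant, hence positive
  definite; the latent correlation `R` is its standardized inverse and
  the partial correlations of `R` equal the plant exactly.  Motifs:
  memory–concentration (0.33) and recovery–mental stamina (0.30) are
  the strongest edges; mental stamina and experience of demands are
  hubs; sleep and irritation/anger attach weakly.
- **Longitudinal dependence.**  Subject effect `u_s ~ MVN(0, σ_u²R)`
  shared across waves plus wave noise `MVN(0, R)`, scaled by
  `1/√(1+σ_u²)` so every wave is marginally `N(δ_t, R)`: the
  cross-sectional structure is exactly `R` at every wave, and the
  within-subject across-wave latent correlation is `σ_u²/(1+σ_u²)`
  (0.2 at the default σ_u = 0.5; the default is a free choice, as no
  empirical across-wave correlation target exists).
- **Marginals.**  Per-item thresholds are spaced as score-boundary
  quantiles of a normal with the item's baseline target mean and SD,
  then anchored, and per-wave latent shifts are solved by root finding
  (closed-form normal arithmetic) so expected item means hit the
  declining targets at every wave; the totals' baseline target
  (≈ 34.8) follows by summation.  Calibration is deterministic and
  cheap, so it runs inside `default_config()` rather than being pasted
  as constants.
- **Heterogeneity.**  An improver class (proportion 0.42) receives an
  extra −1.0 SD latent offset at follow-up only; the follow-up shift is
  solved on the mixture so marginal means stay on target.  The offset
  value was chosen so that the clinical responder criteria recover
  roughly the mixture proportion (responder fraction ≈ 0.37–0.42 of
  classified subjects at the defaults).
- **Attrition** is record-level MCAR with per-wave probabilities
  (1, 9, 28, 49, 132)/915 — enough to exercise complete-case logic;
  no informative-dropout mechanism is modelled.
- **Reproducibility.**  One `numpy` Generator seeded from the config
  drives all draws in a fixed order; identical seeds give byte-identical
  cohorts.

What the generator does **not** emulate, and hence what passing tests
do not show about real data: item-level (as opposed to record-level)
missingness and informative dropout; a general severity factor (its
absence makes synthetic totals less dispersed, SD ≈ 4.5 vs ≈ 6 in real
cohorts, and internal consistency lower, α ≈ 0.47 vs ≈ 0.75); response
styles and item-specific non-normal latents; and any causal coupling
between symptoms over time.  Because ordinal discretization attenuates
rank correlations slightly, Spearman-based estimates are mildly biased
toward zero relative to the latent truth; at the default structure this
contributes well under 0.02 RMSE, absorbed by the 0.03 recovery
tolerance at n = 5,000.

## Problem sizes and numerical checks

Dual-route oracles validate the core algebra: precision-inversion
partials against least-squares residualization (1,000 random PD
matrices, 3–9 variables, agreement to 1e−10), and Dijkstra/Brandes
centralities against exhaustive simple-path enumeration on ≤ 6-node
networks.  Calibration checks run at n = 50,000 (marginals), n = 5,000
(recovery), n = 500 × 2 groups × 500 permutations × 500 repetitions
(type-I error of the comparison test, nominal 5% within [0.03, 0.07]),
and 20 repetitions of case-dropping at n ∈ {200, 2,000} with
B_per = 200 (stability ordering).  These sizes keep a full validation
run to minutes on one CPU while leaving comfortable statistical margins;
`scripts/acceptance.py` uses reduced replicate counts (B = 2,000
permutations, B_per = 250) for its study-scale pipeline pass.

## Known limitations

- Polychoric correlations, regularized (EBIC-lasso) estimation and
  mixed graphical models are out of scope; partial Spearman networks
  are the single estimator.
- Centrality variants (expected influence, bridge centrality) are not
  implemented.
- The matched-group comparison inherits the usual caveat that excluded
  severe cases restrict generalizability; the pipeline reports the
  exclusion bookkeeping so users can see what was dropped.
- CS coefficients are reported without a confidence interval (see
  above); treat small differences between CS values as noise.
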