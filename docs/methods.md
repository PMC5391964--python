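# Methods

## Model

A circuit is a directed signed graph of genes. Each gene's level `x_i`
(arbitrary expression units; only ratios are meaningful) follows

    dx_i/dt = g_i * Π_{j→i} HS(x_j; X0_ji, n_ji, λ_ji) − k_i x_i

with the shifted Hill function

    HS(x; x0, n, λ) = λ + (1 − λ) / (1 + (x/x0)^n).

`HS` equals 1 with the regulator absent and λ at saturation, so λ > 1
encodes activation and 0 < λ < 1 inhibition. Multiple regulators combine
multiplicatively. The basal rate is derived as `g_i = G_i / Π λ⁺` over the
gene's activators, which makes `G_i` exactly the maximum production rate —
the product rule is the unique combination under which that identity
holds, which is why it is used for multi-regulator genes. Hill exponents
are integers and evaluated with exact integer powers.

MicroRNA links in the EMT fixture are modeled with the same Hill kinetics
as transcriptional links; mechanistically distinct translational
repression is out of scope.

## Parameter randomization

Per model, five parameter classes are drawn (defaults in parentheses):

| parameter | range | notes |
|---|---|---|
| maximum production G | 1–100 | per gene |
| degradation k | 0.1–1 | per gene |
| Hill coefficient n | integers 1–6 | per edge, discrete uniform |
| fold change λ⁺ | 1–100 | activating edges |
| fold change λ⁻ | via 1/λ⁻ ∈ 1–100 | inhibitory edges, i.e. λ⁻ ∈ [0.01, 1] |
| threshold X0 | (0.02–1.98) × M | M = regulator's estimated median |

Sampling the *inverse* of λ⁻ concentrates inhibitory fold changes near
strong repression; the median of λ⁻ is 1/50.5 ≈ 0.0198 (the mean is
≈ 0.047 — the two are easily conflated when this scheme is described as
giving a "mean" of about 0.02; the implementation samples 1/λ⁻ uniformly
and documents the median, which is the quantity that is ≈ 0.02).

An unregulated gene's steady level G/k therefore spans a 1,000-fold range
(1 to 1,000) across the ensemble.

### Half-functional rule

Thresholds are chosen so that each link is active in roughly half of all
stable states. Per gene a single-pass mean-field estimate is used: every
regulator's level is approximated by the unregulated steady-state
distribution G/k (median M0, ≈ 92 under the defaults), inward thresholds
are drawn from (0.02–1.98)·M0, inward n and λ per the table, and the
gene's closed-form steady level g·ΠHS/k is sampled
(`median_estimation_samples` = 10,000 draws); the median of that
distribution is the gene's M. Feedback loops are deliberately *not*
iterated to a fixed point — each gene is estimated once with isolated
regulators. Thresholds of the gene's outgoing links are then drawn from
(0.02–1.98)·M. Empirically the per-edge above-threshold fraction across
stable states lands at 0.45–0.55 on the toggle-switch ensembles.

### Distribution variants

Besides the uniform default, draws can follow a Gaussian (mean at the
interval midpoint, sd = width/4, truncated to the interval by resampling)
or an exponential (anchored at the interval minimum, mean = width/4,
truncated at the maximum by resampling). `range_shrink` ∈ {1, 1/2, 1/4}
narrows the uniform interval about its midpoint, halves the Gaussian sd,
or halves the exponential mean per step. Hill coefficients stay discrete
uniform under every variant, and threshold scalings are always drawn
uniformly on (0.02, 1.98)·M: an asymmetric draw (a minimum-anchored
exponential in particular) pushes thresholds far below the regulator's
median and silently breaks the half-functional rule, collapsing the
toggle switch's two states into one diffuse cloud — the symmetric
threshold draw is part of the half-functional machinery, not a
randomized parameter class. These parameterizations are a design choice:
only the distribution shapes and the factor-two shrink protocol are
prescribed, not their numeric parameters.

## Steady-state enumeration

Each model is relaxed from `n_initial_conditions` = 200 starting points
drawn log-uniformly inside the analytic box of reachable steady levels
(`x_max = G/k`; `x_min = x_max · Πλ⁻ / Πλ⁺` over the gene's inhibitors
and activators). With 200 starts, a state holding a 1% basin share is
missed with probability below 1e-8 per model. Initial conditions are
drawn row by row, so enlarging the count extends the same sequence.

Integration uses an adaptive explicit Cash–Karp Runge–Kutta 4(5) scheme
(local tolerance rtol 1e-6); the contract is the residual bound, not the
scheme. A trajectory counts as converged when max_i |dx_i/dt| / x_i falls
below 1e-6; the time horizon is t = 500 with the degradation rates'
slowest timescale at 10. Endpoints (converged or timed out) are merged
greedily at an RMS log10 distance of 1e-2 — candidates sit within ~1e-5
of their root while distinct attractors are separated by orders of
magnitude, so greedy merging is equivalent to single linkage here. Each
merged candidate is polished by Newton iteration to a residual below
1e-10 relative to the turnover k·x, then certified by the Jacobian:
states are kept only if every eigenvalue's real part is below −1e-8;
marginal cases (|Re| < 1e-8) are excluded from state counts and logged.
Convergence alone is not trusted because a slow saddle passage is
indistinguishable from an attractor on any finite horizon.

Oscillation detection (off by default) integrates past a transient with
a fine fixed-step RK4 recorder and accepts a limit cycle when inter-peak
intervals on the widest-swinging gene agree to a coefficient of variation
under 5%; the period and time-averaged levels over whole periods are
reported. The three-gene repressilator in a strongly inhibiting symmetric
regime is the reference case.

## Ensemble orchestration

`run_ensemble` estimates the threshold medians once (child stream 0 of
the master seed), then model i draws its parameters and initial
conditions from child stream i+1, making results independent of execution
order and restartable. The expression table holds one row per stable
state (a model with m states contributes m rows, unweighted; no
basin-size weighting), the parameter table one row per model. Models
with no stable state are flagged and excluded from the expression table
but kept in the parameter table. Knockdown (overexpression) divides
(multiplies) the targeted gene's G and derived g by the factor and
touches nothing else, so paired perturbed/unperturbed runs with shared
seeds differ only through the perturbed parameters.

## Statistics

Expression rows are log10-transformed and z-scored per gene before
clustering — raw levels span three decades and Euclidean distances would
otherwise be dominated by high-expression genes. (Whether to standardize
per gene or globally is a choice; per gene is used and recorded here.)
Hierarchical clustering is average linkage on Euclidean distance;
PCA uses a deterministic sign convention (largest-magnitude loading
positive). Per-(cluster, gene) LOW/INTERMEDIATE/HIGH calls compare the
cluster median against the full-ensemble terciles, making the calls
invariant under monotone per-gene rescaling; tercile boundaries are a
design choice standing in for a visual assignment.

### Counting major gene states

For unattended runs, `major_gene_states` scans dendrogram cuts from 2 to
40 clusters; at each cut, clusters holding at least 5% of rows are
reduced to a discrete H/I/L signature (median z-score against a ±0.3
band), so sub-clusters of one state collapse onto a single signature
while states differing by a flipped switch remain distinct. The signature
count sustained over the longest range of cuts is the state count, and
the states are read off at the shallowest such cut. This plateau scheme
is robust to average linkage's habit of splitting isolated outlier rows
off first, which defeats naive "largest k with all clusters above 5%"
rules. Known limitation: on two-gene circuits the state clusters are
elongated continua (levels inside one state span decades), so sub-regions
with intermediate signatures can exceed 5% occupancy and the heuristic
may report one or two extra states; for such circuits the intended
cluster count should be passed explicitly, and the robustness tests
verify the two mirror states directly at k = 2. Density-based
(HDBSCAN-style) and Gaussian-mixture/BIC counters were evaluated as
alternatives; the former merges the cascade intermediates of coupled
switch chains into the extremes, the latter over-segments them.

## Fixture circuits

TS, TS1SA, TS2SA and the repressilator are constructed programmatically.
The coupled toggle-switch chain CTS(k) couples consecutive switches
directionally (Ai activates Ai+1; Bi+1 activates Bi): exactly one
domain-wall orientation is then unfrustrated, so the chain supports the
two aligned extremes plus one intermediate state per junction — k+1 gene
states in which consecutive switches flip one at a time. Bidirectional
coupling was examined and yields walls of both orientations (more than
k+1 states), contrary to the cascade the fixture is meant to embody.

The 22-node / 82-edge EMT circuit is a synthetic reconstruction (the
curated edge list it stands in for was not redistributable): canonical
interactions arranged as a cascade of three mutual-inhibition switches —
miR-34a/SNAIL, miR-200b,c/ZEB1, miR-200a,miR-141/ZEB2 — with TGFB1
(repressed by the miR-200 family, inducing SNAI1 and the peripheral TFs)
closing the backward feedback, ten repressors on CDH1, eleven activators
on VIM, and miR-30c/miR-205/miR-9 as pure inputs. Every edge is annotated
in `data/emt22_synthetic.topo`. The circuit reproduces the qualitative
phenotype structure (E, M, two hybrid E/M with SNAIL active before ZEB)
but is *not* the literature-curated network; quantitative EMT conclusions
should not be drawn from it.

## What the generator does and does not emulate

The synthetic ensembles emulate kinetic heterogeneity across cells or
conditions as parameter randomization around a fixed topology. They do
not emulate molecular noise (no stochastic dynamics), explicit
mRNA/protein stages, delays, or mechanistic microRNA kinetics, and no
real expression data enters anywhere; passing tests demonstrate
topology-driven statistical structure, not agreement with any particular
biological dataset.

## Problem sizes

Default ensembles are 10,000 models (used by `scripts/acceptance.py`).
The test suite runs 2,000-model ensembles for toggle-switch and coupled
toggle-switch statistics, 10,000 for the one-sided self-activation motif
(to resolve its ~1% tristable fraction), 2,000 for the EMT circuit
(below ~2,000 models the 6–12% hybrid clusters sit too close to the 5%
major-state line for the plateau count to be stable) and 700 per
sampling-variant combination; at these sizes the Monte-Carlo standard
errors are several times smaller than the asserted tolerances.
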