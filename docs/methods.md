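# Methods

`mvsim` generates benchmark datasets for multi-view (gene + miRNA) omics
analysis methods.  Because real multi-omics datasets are rarely annotated
well enough to score a feature-selection or network-inference method against
a known answer, the package builds the answer first — a regulatory network
with known interaction semantics and kinetics — and then simulates noisy
expression measurements from it.  This note records the model, the defaults,
and the design choices that were genuinely open.

## 1. Network construction by score-guided motif replication

The generator grows a directed network over a fixed node set of `n_genes`
gene nodes and `n_mirnas` miRNA nodes, starting with no edges.  Construction
is iterative:

1. A pool of `pool_size` (default 10) random motif templates is drawn from
   the registry: autoregulation, feed-forward loop (coherent or incoherent),
   2–3-node feedback loop, single-input module (fan-out 2–5), dense
   overlapping regulons (2–4 regulators × 2–4 targets, ~75 % wiring
   density), and the miRNA-containing feed-forward and feedback variants.
   Each template has exactly one master-regulator slot `x`.
2. Each pooled motif is scored by how much assigning its slots would move
   the network's degree distribution toward target laws.  Gene (total)
   degrees chase a power law `d_p(k) ∝ k^-alpha` (default `alpha = 2.2`,
   the empirical scale-free range being 2–3); miRNA in-degrees chase the
   same power law, and miRNA out-degrees chase an exponential law
   `d_e(k) ∝ exp(-lambda k)` (default `lambda = 0.5`, giving typical miRNA
   regulons of a few targets).  The per-candidate sub-score sums, over every
   degree bin, the signed normalized discrepancy reduction
   `sign(|d_k - p_k| - |d_k - f_k|) · |d_k - p_k| / d_k`, where `p` is the
   current degree-fraction vector and `f` the hypothetical one after the
   assignment.  Only the two bins the move touches contribute, which is what
   makes scoring O(candidates) instead of O(candidates × bins).
3. A motif is selected with probability proportional to its score; because
   scores are signed, weights are shifted up only when the pool minimum is
   negative (plus a 1e-6 epsilon so all-zero pools sample uniformly and
   every candidate stays reachable).  Concrete nodes are then sampled for
   the slots by the same rule applied to their sub-scores, without
   replacement within one instance.
4. Template edges are added with their signs; miRNA-source edges are always
   repressive.  Every new edge receives its own Hill threshold and
   steepness, sampled at construction.  Duplicate edges are skipped (first
   writer wins); self-loops arise only from the autoregulation template.
5. Consumed nodes leave the available pool; the `x` node is parked in a
   separate set `H`.  When the pool is empty, `H` becomes the next level's
   pool.  Recycling the master regulators is what wires modules into a
   hierarchy and concentrates degree on a few multi-level hubs.

Termination: each recycling round strictly shrinks the pool because motifs
return at most one node (the `x`) out of the ≥ 1 they consume.  Two guards
cover the degenerate cases: templates none of whose slot kinds are available
are never pooled, and a round that returns as many nodes as it started with
(only possible if every instance was single-slot) stops recycling outright.
When the remaining nodes cannot fill a template, the largest fillable subset
of slots is instantiated (partial-motif fallback).

Signalling nodes — exogenous experimental inputs — are attached last.  They
have only outgoing edges; each signal gets 1–3 targets drawn proportionally
to (out-degree + 1).  The +1 smoothing keeps leaf nodes eligible while still
preferring hubs, so that a signal can actually steer the network state.
Pure proportionality would make zero-out-degree nodes permanently
unreachable, which seems an artifact of wording rather than intent.

### What the generated topology does and does not reproduce

Pooling the per-network (log degree, log frequency) histogram points of 50
networks of 1000 nodes built at `alpha = 2.2` and fitting one line yields a
slope magnitude near 2.3–2.5 with R² ≈ 0.89–0.94 (the acceptance script
recomputes this).  The realized exponent deviates from the input `alpha`
because motif structure, not preferential attachment, produces the tail.

The clustering-coefficient curve `C(k)` (mean over nodes of total degree
`k`; directed convention `C = n / (k(k-1))` with `n` the directed edges
among the `k` distinct neighbours) decays as a power law whose exponent is
statistically independent of network size over sizes 10–500 — the
hierarchical-modularity signature.  The exponent magnitude itself averages
≈ 1.8 rather than the ≈ 1 reported for real transcriptional networks:
triangles here come only from loop-type motifs, so hub triangle counts grow
more slowly than hub degree.  This is a known limitation of the motif
catalogue, not of the scoring machinery.

## 2. Dynamics

Concentrations are dimensionless and O(1).  Each gene `i` obeys

    dx_i/dt = p_i · r_i(x) − d_i(m) · x_i

with production modulation `r_i ∈ [0, 1]` and degradation `d_i`.  The
elementary regulation term is the Hill function
`h(x; θ, μ) = x^μ / (x^μ + θ^μ)`; `θ` is the half-activation threshold
(sampled per edge from [0.3, 0.8]) and `μ` the steepness (from [2, 10]).
Numerically `h` is evaluated as `1 / (1 + (θ/x)^μ)`, which is exact at
`x = θ` and immune to `x^μ` overflow.

Multiple regulators combine through a random binary composition tree whose
internal nodes are the four interaction combinators, each mapping
[0,1]-valued inputs to [0,1]:

* COOP(a, …) = min — all regulators required;
* SYN(a, …) = min(1, Σ) — any regulator suffices (binary nesting of the
  capped sum is exact, so the tree shape does not change the value);
* INH(a) = 1 − a — repression;
* COMP(a, b) = max(0, a − b) — an activator competing with one repressor
  (strictly binary).

Activating edges enter as Hill leaves.  Repressive gene edges enter either
as the second argument of a COMP wrapped around an existing subtree (with
probability ½ when one exists) or as INH leaves; remaining subtrees are
merged pairwise by COOP or SYN chosen uniformly.  The composition
distribution is not specified by the biology; the binary-tree choice is a
design decision, flagged as such.  Every in-edge appears exactly once as a
leaf, with its own per-edge Hill parameters.

miRNA regulators of a gene do not enter the production tree: they raise the
degradation rate, `d_i = d_i0 + d_gain · SYN(h(m_1), …, h(m_q))` —
synergistic inhibition being the assumed mode of joint miRNA action.  miRNA
nodes themselves are produced like genes (their own tree over TF in-edges)
but degrade at the constant basal rate.  Signals are exogenous: their
trajectories substitute the Hill-leaf input and they carry no state.

Kinetic defaults (per node): basal degradation `d0 ~ U(0.1, 1)` per time
unit; production `p = U(0.5, 1.5) · d0` so unregulated steady states
`p/d0` land near 1, on the scale the Hill thresholds expect; miRNA
degradation gain `U(0.5, 2) · d0`, so full miRNA repression can at most
triple the turnover rate.  The rates keep all timescales O(1)–O(10) over
the default horizon.

## 3. Simulation and datasets

The system is integrated with LSODA (adaptive, stiffness-switching;
`rtol 1e-6`, `atol 1e-8`), retrying with BDF on failure; tiny negative
solver excursions are clipped to 0 on output.  The default grid is 100
equally spaced points on [0, 50] time units — long relative to `1/d0`, so
the last time point approximates steady state for non-oscillating nodes.
The initial state defaults to 0.1 for every node.  A steady-state sample is
the last row of the trajectory, split into the gene view and the miRNA view.

Conditions are signal programs: constant (including 0 for knock-down-style
inhibition), periodic (rectified sine or square, emulating repeated dosing),
piecewise-linear custom trajectories, or condition-level random constants
drawn from U(0, 1).  A dataset is generated subject by subject: all kinetic
and Hill parameters are jittered multiplicatively by `(1 + ζ)`,
`ζ ~ N(0, sigma_bio)` (default 0.05, truncated at 1e-6 to preserve
positivity) — the biological replicate variability; the jittered system is
integrated; the last time point is kept.  Measurement noise is then applied
element-wise to the assembled matrices:

    y = c + x · e^η + ε,   ε ~ N(0, σ_ε), η ~ N(0, σ_η)

with defaults `c = 0`, `σ_ε = 0.05`, `σ_η = 0.1` (the error-model structure
is standard for intensity data; the levels are package defaults, chosen so
the additive floor is visible at low expression without drowning the
signal).  Observed intensities may be negative; no clipping, matching how
such data behave.  Negative-binomial count noise, batch effects and
probe biases are out of scope.

A `SeedSequence` spawned from one root seed drives construction, model
sampling and simulation separately, so a bundle is reproducible
byte-for-byte from its provenance file.

## 4. Validation metrics

* Degree-law fits use OLS on (log k, log frequency) over non-empty integer
  bins — a line fit, deliberately, rather than maximum-likelihood power-law
  estimation, because the quantities being reproduced are line-fit
  estimates.  For replicate sets, each network contributes its own
  histogram points to one pooled fit, so reproducible head bins are
  weighted by replication instead of being swamped by rare tail bins.
* `C(k)` exponents: mean C per degree, log-log OLS; the scale-invariance
  check regresses per-network exponents on size (OLS, 95 % CI).
* Path-length profiles classify candidate edge lists against the ground
  truth by directed shortest-path length (1 = direct, > 1 = indirect,
  Inf = absent); self-pairs count as direct only via a self-loop.

## 5. Problem sizes used in tests

The test suite exercises the full pipeline at reduced scale chosen to keep
a laptop run comfortable: degree-law recovery on 10 networks of 500 nodes,
scale invariance on 30 networks of sizes 10–500, and the GRN3 benchmark
profile (500 genes, 100 miRNAs, 20 signals) for the end-to-end dataset
contracts with 100- and 75-subject designs.  The acceptance script runs the
full 50 × 1000-node degree-law experiment.

## 6. Known limitations

* The C(k) exponent magnitude (~1.8) overshoots the ~1 of real TRNs, as
  discussed above.
* Simulated steady states ignore oscillatory attractors: the last-time-point
  convention samples an arbitrary phase for oscillating subnetworks (the
  jitter turns this into extra between-subject variance, which is arguably
  realistic but not controlled).
* The generator's degree guidance treats gene degree as undirected
  (total degree); in/out structure of gene nodes is shaped only by the
  motif templates.
* Synthetic subjects are exchangeable — no population structure, covariates
  or batch effects — so methods that exploit such structure cannot be
  benchmarked with these data.
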