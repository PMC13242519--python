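# Methods

`grnloop` builds signed gene regulatory networks (sgGRNs) by coupling a
knowledge provider — a live LLM assistant or a deterministic offline mock —
to an ODE model that is fitted against time-resolved expression data. This
note records the model, the conventions, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Data model

Expression data enter as per-gene, per-time-point summaries on a normalized
[0, 1] scale. Starting from cell-by-gene count tables (one per time point),
the preprocessing chain is:

1. **Cell/gene filtering** — cells with < 200 detected genes are dropped,
   then genes present in < 3 of the *retained* cells. The order (cells
   first, then genes) matters and is fixed; reversing it changes which genes
   survive.
2. **Library-size normalization** — every cell is scaled to a total of
   30,000 counts; all-zero cells are left untouched (with a warning).
3. **Per-gene normalization** — values are log1p-transformed and divided by
   the gene's maximum log1p value taken across *all* time points, so each
   gene's trajectory lies in [0, 1] and peaks at 1 somewhere. (Normalizing
   per time point instead would destroy the time structure; the
   global-over-time maximum is the only reading that keeps trajectories
   comparable across time.)
4. **Summaries** — per (gene, time point): the mean of the normalized values
   and the effective standard error `SE_eff = SD / sqrt(N_eff)` with the
   sample SD (ddof = 1). A group with a single value gets SD = 0 and a
   warning; zero SEs are floored at 1e−6 so chi-square weights stay finite.

`N_eff` (default 15) deliberately understates the number of cells: cells
from one dissociation are not independent biological replicates, so using
the true cell count would produce absurdly small error bars. The flat
`N_eff` is used for every group regardless of actual cell count; a
`min(n_cells, N_eff)` variant is available behind a flag. Genes missing at a
time point yield a *missing record*, never an imputed zero; the fit simply
skips those residuals (reducing n).

## ODE model

A signed adjacency matrix A (entries in {−2, −1, 0, 1, 2}; A[u, v] is the
edge gene_u → gene_v; ±1 direct, ±2 indirect regulation) is translated into
additive Hill kinetics. For gene i:

    dx_i/dt = b_i
            + Σ_{j ∈ Act(i)} a_ij · H(x_j; h_ij)
            + Σ_{j ∈ Inh(i)} a_ij · (1 − H(x_j; h_ij))
            + Σ_{e ∈ Stim(i)} s_e · b_ie · u_e(t)
            − δ_i · x_i,        H(x; h) = x^h / (K^h + x^h),  K = 0.5.

Parameter classes, units (per day for rates, dimensionless otherwise) and
default bounds:

| class   | meaning                   | bounds     | start sampling |
|---------|---------------------------|------------|----------------|
| a_i_j   | edge strength             | [0, 50]    | log-uniform    |
| h_i_j   | Hill exponent             | [1, 10]    | uniform        |
| b_i     | basal production          | [0, 5]     | uniform        |
| b_i_e   | stimulus-driven production| [0, 5]     | uniform        |
| δ_i     | first-order decay         | (0, 50]    | log-uniform    |

Choices worth stating:

- **K = 0.5** pins the Hill threshold at the mid-range of the normalized
  data, which makes `h` interpretable as switch steepness on the data scale
  and removes one unidentifiable parameter per edge.
- **Indirect edges** (±2) that survive pruning enter the kinetics exactly
  like direct ones; a lumped-delay treatment is out of scope.
- **Stimulus** `u_e(t) ≡ 1` for treated experiments (a treatment applied
  throughout the time course), 0 otherwise; each stimulated gene gets its
  own production strength `b_i_e`. An inhibitory stimulus enters with a
  negative sign and can in principle violate non-negativity; the shipped
  generators use activating stimuli only.
- **Initial conditions** are fixed to the observed means at the first time
  point rather than fitted — this keeps k small and the printed parameter
  counts honest. Free parameters: k = 2·(#genes) + 2·(#edges) + (#stimulus
  links).
- The RHS lives behind a single `rhs` interface so alternative kinetics
  (e.g. multiplicative gating) can be swapped without touching fitting.

User-supplied bounds are clamped into the table above before any fit, with
a warning (sanity bounds).

### Integration

The reference integrator is LSODA (stiff-capable, `scipy.solve_ivp`,
rtol 1e−8 / atol 1e−10) behind `simulate`. The fitting objective instead
uses a numba-compiled adaptive Dormand–Prince 5(4) stepper specialised to
this RHS: a fit performs ~10⁴ integrations (finite-difference jacobians ×
multi-start), and the compiled path is 15–30× faster. The test suite
asserts agreement between the two integrators to ~1e−6 on random models; a
pure-Python fallback keeps everything working without numba. Integration
failures raise, and inside the optimizer they surface as large residuals so
a pathological parameter region is abandoned rather than crashing the fit.

## Fitting and model selection

Residuals are `(simulated − mean) / SE_eff` per non-missing record;
chi² = Σ r². Fitting is multi-start bounded least squares (`trf`):
start vectors sampled reproducibly from a seed (log-uniform for a/δ,
uniform for h/b), each refined, best chi² wins. Two budget controls exist
for large sweeps, both off by default:

- `refine_top = m`: screen starts by their initial objective and refine only
  the best m (the "identify promising initial values, then estimate"
  reading of multi-start);
- `ftol` looser than 1e−8: stop refinements that have plateaued.

`informed_start` adds one deterministic, topology-agnostic start: basal
production set to each gene's mean expression with unit decay (the
uncoupled steady state then equals the mean), all couplings weak, Hill
exponents mid-range. Because it is built from the data alone, it treats
competing topologies identically; it mainly rescues the optimizer from the
notorious multi-start lottery on coupled ODE landscapes.

**L1 reduction** is a three-stage protocol: (1) fit with penalty
λ·Σ|θ| (λ default 50) on parameters with prefixes a_, b_, h_, δ_, the
absolute value smoothed as sqrt(θ² + ε²), ε = 1e−8, so the bounded
optimizer sees a smooth objective (implemented as appended residuals
sqrt(λ·|θ|), so Σr² reproduces the penalty); (2) every penalized parameter
with |θ̂| below the threshold (default 10, compared on the native linear
scale) is *fixed at its L1 estimate* — not zeroed; (3) the remaining free
parameters are refitted without penalty from the L1 solution. Edges whose
strength parameter stayed free are reported as the kept interactions. If
the refit chi² is essentially the L1 chi², the fixed parameters were
redundant and the structure is stable under reduction.

**Goodness of fit**: dof = n − k; p is the upper chi-square tail at the
observed chi² (probability of the misfit under pure white noise given the
additive Gaussian error model); AIC = chi² + 2k; BIC = chi² + k·ln n;
AICc = AIC + 2k(k+1)/(n−k−1) when defined. The AICc form is not uniquely
determined by "corrected AIC" alone; this form reproduces the reference
statistic triples asserted in the tests exactly. Ties in the
per-gene chi² argmax are broken alphabetically (with a warning).

## The back-loop

One refinement iteration: (1) the gene with the largest summed chi²
contribution is the target; (2) its needed regulation is classified from
the ratio mean(simulated)/mean(experimental) — ratio > 1 means the model
overestimates, i.e. inhibition is missing; ratio ≤ 1 means activation
(a zero experimental mean falls back to the sign of the simulated mean,
with a warning); (3) the provider is asked for one upstream regulator
acting in that direction, excluding genes already in the network; (4) an
accepted symbol (present in the measured dataset after synonym mapping)
spawns 2N+1 ordered query pairs, whose verdicts extend the adjacency
matrix — verdicts from earlier rounds are immutable; (5) the matrix is
pruned and the model refitted. The loop stops at p ≥ α (default 0.05),
an EMPTY answer, an iteration cap (default 10), or no chi² improvement
for `patience` (default 2) iterations. α ≥ 1 trivially accepts the first
fit.

A subtlety the planted-regulator harness is built around: because every
gene carries a free basal-production parameter, weighted least squares
nearly matches each gene's mean, so the sim/exp ratio of a badly fitted
gene sits close to 1 and its *sign* is driven by the shape of the
transient, not by the sign of the missing regulation. For data with a
delayed onset, the best reduced fit overshoots the early low phase —
ratio > 1, verdict "inhibition". The harness therefore plants the withheld
regulator as a slowly decaying repressor: its fall through the Hill
threshold releases the target (delayed rise), and the heuristic's answer
matches the planted edge sign. This is the regime in which the
ratio heuristic is self-consistent; users should expect the heuristic to
be unreliable when a gene's misfit is a pure transient-shape mismatch.

**Pruning**: an indirect edge (±2) i → j is removed when j is reachable
from i via a path (≥ 1 edge) of direct edges of the *same sign class only*
(+2 needs an all-+1 path, −2 an all-−1 path; BFS reachability). All
removals are evaluated on the input matrix and applied simultaneously, so
order cannot matter; a ±2 self-loop is removed only via a same-sign direct
cycle. Mixed-sign paths never qualify, even when their sign product
matches — the rules are sign-pure by construction. Pruning is optional and
on by default.

**Lever analysis**: for each poorly fitted target, every parameter feeding
it (incoming-edge a/h, own b/δ/b_i_e) is scaled by factors (default 0.25,
0.5, 2, 4; values clipped into bounds), the system re-simulated, and the
change in the target's peak, trapezoidal AUC and chi² contribution
recorded; rows are ranked by chi² improvement. Factor 1 reproduces the fit
bit-for-bit, so its deltas are exactly zero — a useful self-test.

## Null benchmark

Random surrogate topologies preserve, relative to a reference: node set,
edge count, self-loop count, zero-in-degree count, and (by default) the
multiset of edge signs — so every benchmarked model has identical n and k
and the information criteria rank rows exactly as chi² does. Surrogates
are rejection-sampled (self-loop positions, then off-diagonal positions,
then a random permutation of the sign multiset; accept when the
zero-in-degree count matches) and carry only direct (±1) edges: the
direct/indirect distinction is knowledge provenance and has no meaning for
a rewiring. Sign-multiset preservation keeps the parameter-bounds profile
identical; a flag randomizes signs instead.

The shipped benchmark harness fits all models — reference and surrogates —
with one shared convention: Hill exponents fixed at 3 (removing the least
identifiable parameter class from the comparison; k stays equal across
rows), 16 starts including the data-informed one, top-4 refinement. The
reference scenario generator requires a mostly regulated sparse network
(between n+1 and 1.5n edges, at most one root): a reference whose genes
are mostly unregulated roots produces data that any topology fits equally
well, and the comparison would measure optimizer noise instead of
structure.

## Synthetic data

The generator plants a random signed digraph with kinetics drawn to make
regulation — not basal leak — shape the dynamics: δ log-uniform in
[0.4, 2.5]/day, basal b in [0.01, 0.06], per-edge strength
(0.7–1.4)·δ_target/indegree (so steady states stay inside [0, 1]), Hill
exponents in [2, 6], initial states spread over [0.05, 0.9]. Time grid:
0, 0.5, 1, 2, 4, 7, 10 days (seven points). Latent genes are bridges
observed → latent → observed visible only to the knowledge base; a
sign-pure two-hop path induces an indirect verdict with the *product* sign
— note this is more general than the pruning rules, which only remove
sign-pure redundancies, so a −2 verdict induced by a (+,−) bridge
legitimately survives pruning.

Measurement noise is Gaussian on the normalized scale, applied to the
per-(gene, time) mean with sd `noise_sd / sqrt(N_eff)`; the reported
SE_eff equals that same value, so fitted chi² values are calibrated to
their degrees of freedom (asserted over 20 seeds). `noise_sd` plays the
role of the per-cell spread (default 0.1, i.e. SE_eff ≈ 0.026 at
N_eff = 15, the magnitude real normalized single-cell summaries show).
At `noise_sd = 0` the means equal the truth exactly and SE_eff falls back
to a nominal 0.05 so chi-square weights stay defined.

What passing synthetic tests do **not** show about real data: no dropout,
no library-size variation beyond the basic count variant, no batch
effects, Gaussian rather than count noise at the summary level, a
knowledge base that is right (or wrong) by construction rather than by
literature, and identifiable, low-dimensional ground truths. The harnesses
demonstrate the machinery is correct and self-consistent, not that the
inferred biology of any particular dataset is.

## Problem sizes and determinism

Shipped test/harness sizes (the package's own scale choices): parameter
recovery on 3 genes (16 starts noise-free; 20 seeds for calibration), loop
recovery on 5 genes × 20 seeds, null benchmark on 8 genes × 10 replicates
× 10 surrogates. Every stochastic component (start sampling, truth
generation, noise, surrogate topologies, mock corruption) is a pure
function of an integer seed; mock answers are additionally independent of
query order (per-query hashed RNG streams). Reruns with equal seeds are
bit-identical.

## Known limitations

- The additive Hill RHS is one defensible choice; published parameter
  counts from other toolchains need not match ours for the same topology.
- The ratio-based regulation heuristic is unreliable for transient-shape
  misfits (see above).
- The L1 threshold (|p| < 10) is tuned to parameter scales of the original
  bounds; on well-normalized synthetic problems (parameters O(1)) it fixes
  everything, so harnesses use thresholds matched to their scale.
- No profile-likelihood identifiability analysis; multi-start bookkeeping
  is the only convergence diagnostic.
- Live-provider code paths (HTTP, retries, transcripts) are exercised only
  against fixtures; no test requires network access.
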