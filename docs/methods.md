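# Methods

## Model

A B-cell receptor lineage is summarized as parent–child pairs (PCPs): the
nucleotide sequences at the two ends of each edge of a clonal-family tree,
plus an evolutionary time `t` for the edge.  Somatic hypermutation (SHM) is
modeled as an independent Poisson process at each nucleotide site `i` with
rate `λ_i` and a conditional substitution distribution `s_{i,b}` over the
three non-parent bases.  Over a branch of length `t` the probability that
site `i` is unchanged is `exp(-λ_i t)` and the probability it ends as base
`b` is `(1 - exp(-λ_i t)) s_{i,b}`.  The probability of any codon-level
transition is the product of its three per-position terms, so multi-nucleotide
codon changes arise only as co-occurring independent single-site events; no
clustered-mutation process is modeled.  Only the product `λ_i t` is
identified: rates and branch lengths share one arbitrary unit.

Selection enters as a per-codon-site factor `f_j(X̄) ≥ 0`, a function of the
entire parent amino-acid sequence `X̄`, that multiplies the neutral
probability of a *nonsynonymous* substitution at site `j`.  `f_j > 1` is
diversifying selection, `f_j < 1` purifying, `0` the strongest possible
purifying selection — a probability-scale analogue of dN/dS.  At the codon
level, codons coding a non-parent amino acid are scaled by `f_j`, synonymous
codons are left at their neutral probability (synonymous factors pinned at 1),
stop codons get probability 0, and the parent codon absorbs the remainder.

Because `f_j` is unbounded, a scaled probability can exceed 1; the total
non-parent mass at a site is then clamped to `1 - 1e-6` and the event is
counted.  The clamp fraction is reported by the fitting routines; on data
simulated at realistic branch lengths it stays at ~1e-4 or below.

## Two likelihoods, one fit

Two objective functions coexist deliberately:

* **Selection-model training** uses a per-site binary cross-entropy on the
  indicator of an amino-acid difference between parent and child, with
  predicted probability `m_j = f_j p_j`, where `p_j` — the neutral
  nonsynonymous sum at site `j` — is precomputed and cached after every
  branch-length round.
* **Branch-length optimization** maximizes the full codon-level likelihood.
  This matters: the amino-acid-level BCE cannot see synonymous substitutions,
  but synonymous changes are exactly what anchors `t` and makes `t` and `f`
  jointly identifiable (a pair rich in synonymous change pulls `t` up and
  pushes factors down).

Fitting alternates the two: each cycle first re-optimizes every PCP's branch
length under the current selection model (ignoring any branch length carried
on the input tree), recomputes the neutral-sum cache, then runs RMSprop
epochs on the BCE.  The default is 4 cycles; the desk-scale experiments in
the test suite use 2 cycles of 1 epoch, which is already past convergence for
the analytic ground truths used there.

## Selection models

Three families share one contract (sequence in, per-site factor out):

* `single` — one trainable factor for all sites of all sequences, the
  repertoire-wide baseline;
* `per_position` — one factor per alignment column, blind to content;
* `transformer` — amino-acid embedding + fixed sinusoidal positional
  encoding, a pre-norm transformer encoder (multi-head self-attention with
  key-padding masking, ReLU feed-forward of width 4x the embedding), a final
  layer norm and a per-site scalar linear head.

Every family emits a raw score passed through the **wiggle** activation,
`exp(wiggle(x, β)) = exp(β(x-1))` for `x < 1` and `x^β` for `x ≥ 1`:
continuous, strictly increasing, equal to 1 at `x = 1`, and sub-linear above
1 so factors cannot run away.  `β = 0.3`, fixed, not trained.  The head bias
is initialized at 1 so a fresh model starts at neutrality (`f ≈ 1`).

The training stack is a small reverse-mode autodiff engine over numpy arrays
(`_nn.py`), gradient-checked against central finite differences in the test
suite.  Float32 is used throughout training; the graph is explicitly released
after each backward pass so activations are freed immediately.

Optimizer defaults: RMSprop, learning rate 1e-3, smoothing 0.99, no gradient
clipping.  A global-norm clip is available as an option but disabled by
default: with ~1e5 parameters a norm-1 clip rescales every step by a factor
of 10–50 and training stalls within any reasonable epoch budget.

## Branch-length solver

The scalar path (`optimize_branch_length`) is bounded Brent minimization of
the codon negative log likelihood on `log t` over `[1e-6, 5]` with tolerance
1e-8; pairs with no substitutions pin at the lower bound and are flagged.
The fitting loop uses an equivalent vectorized golden-section search over all
PCPs simultaneously (28 iterations, ~1e-5 relative precision on `t`),
because one `scipy` call per PCP is two orders of magnitude slower at 1e5
PCPs.  The two agree to better than 1% relative on random PCPs (tested), far
below the ~10–30% statistical error of any single branch-length estimate.
Per-site codon sums are reduced through a single 64x21 codon-to-amino-acid
class matrix, avoiding any per-site 64-vector gathers.

## Simulation

Children are drawn per codon site independently from the mutation–selection
transition distribution (parent codon as remainder mass), a single-step
transition per branch rather than a continuous-time chain — matching the
model that is fitted.  Stop codons have probability zero by construction, so
simulated lineages can never leave frame.  Cascading down a tree, the child
drawn on an edge is the parent of its daughter edges; the standard data
filters (drop naive edges, drop identical pairs) are applied to the output.
Randomness derives per (tree, edge) from one master seed via counter-based
Philox streams, so outputs are byte-identical regardless of traversal or
parallelization order.

## Evaluation metrics

* **Overlap**: per-site observed substitution counts vs expected counts
  (sums of per-PCP `m_j`, with Bernoulli-sum variance `Σ m_j(1-m_j)`),
  summarized as `Σ_j min(obs_j, exp_j) / (½(Σ obs + Σ exp))`.  The headline
  number pools all groups; per-group overlaps are reported alongside.
* **Log-factor R²**: agreement of two models' log selection factors with the
  identity line, pooled over every site of every panel sequence.  Residuals
  are taken to `y = x` (not a refitted regression line); the total sum of
  squares pools both models' deviations from the grand mean, making the
  statistic symmetric in its two arguments — self-comparison gives exactly 1,
  and a constant log-offset has a closed-form penalty used as a test oracle.
* **Weighted Shannon entropy** (bits) of per-site amino-acid count
  distributions, for germline-diversity style summaries.

## Synthetic data: what it emulates, what it does not

The fixture generators produce naive (unmutated ancestor) sequences, random
rooted binary clonal trees with exponential branch lengths, neutral rate
tables, and analytic ground-truth selection functions.  Default study
conditions, chosen once: 60-codon naives at balanced base composition,
50-leaf trees, mean branch length 0.05 (per unit rate), and a complete 5-mer
rate table with log-normal rate heterogeneity (σ = 1, unit mean) emulating
SHM hotspot bias.  Desk-scale experiment sizes: 80k training PCPs (with 5k
and 20k subsets for the data-scaling trend), a 200-sequence held-out panel,
50k PCPs for the self-consistency overlap, 200 PCPs of 300 codons at t = 0.1
for branch-length recovery.

Ground-truth selection functions are analytic rather than a pre-trained
network: `constant`, a positional `sinusoid`, and a `context` rule that
multiplies the sinusoid by a penalty (default 0.5) wherever the current
amino acid is hydrophobic (`AVILMFWC`), clipped to [0.05, 3].  The context
family preserves the property that matters for recovery tests — factors
depend on sequence content, not only position — while remaining exactly
computable.

What passing these tests does *not* show: real repertoires have V(D)J
recombination structure, indels, context dependence wider than 5-mers,
phylogenetic uncertainty and ancestral-reconstruction error, none of which
the generator emulates.  Results on synthetic data certify the machinery
(probability composition, optimization, metrics), not biological conclusions.

## Numerical choices and degenerate inputs

* Probabilities below 1e-300 are flushed to zero; BCE probabilities are
  floored at 1e-12 inside training only (an impossible observed substitution
  in `pcp_loss` yields an infinite loss, surfaced, not clipped).
* Codons containing `N` (and their sites in either sequence of a pair) are
  masked out of every likelihood, gradient, aggregation and simulation;
  an all-ambiguous sequence produces an all-masked profile plus a warning.
  Naive sequences for simulation must be unambiguous (stricter than real
  pipelines, which filter such families upstream).
* Gapped input is rejected, not repaired; indels are assumed reversed
  upstream.
* A k-mer context observed with all occurrences mutated would give an
  infinite rate; the mutated fraction is capped at `1 - 1/(2n)`.
* Unseen k-mer contexts (including sequence ends, padded with N) fall back
  to the table's global average rate and substitution distribution.

## Known limitations

* The 5-mer table provider is a stand-in for richer SHM models (e.g. CNNs
  over wider contexts); fidelity to any published SHM model is not claimed.
  The `NeutralProvider` protocol is the seam for plugging one in.
* Selection factors are per-site scalars; no per-target-amino-acid factors.
* Heavy and light chains are modeled independently; no paired modeling.
* Training is single-CPU numpy; it is adequate for ~1e5 PCPs and ~1e5
  parameters but not for repertoire-scale (~1e6 PCP, ~1e6 parameter) runs,
  which would want a GPU tensor framework behind the same interfaces.
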