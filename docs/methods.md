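# Methods

## Model and scores

A Bayesian network over discrete variables X₁..Xₙ is a DAG plus one
conditional probability table (CPT) per node; the joint factorizes as
P(X₁..Xₙ) = Πᵢ P(Xᵢ | Pa(Xᵢ)). Given complete data D of N cases, the
family counts N_ijk (cases with parent configuration j and value k at
node i, margins N_ij) determine the maximum-likelihood log-likelihood

    LL = Σᵢ Σⱼ Σₖ N_ijk · log₂(N_ijk / N_ij),

with the 0·log 0 = 0 convention and no smoothing: parameters of
unobserved parent configurations (N_ij = 0) are never evaluated and
contribute nothing. All code lengths are in bits; the argmin over
structures is base-invariant, but printed scores are base-dependent, so
every output header records the base.

The model dimension is k = Σᵢ qᵢ(rᵢ − 1), where qᵢ is the product of
the arities of node i's parents (1 for roots) and rᵢ the node's arity.
The five scores are MDL = −LL + (k/2)log₂N, AIC = −LL + k,
AIC2 = −LL + k·log₂e (the AIC penalty restated in bits), MDL2 = MDL/N
(per-case, comparable across sample sizes), and BIC = −MDL (computed as
the literal negation of the same floating-point expression, so the
identity is exact, not approximate). MDL, MDL2, AIC and AIC2 are
minimized; BIC is maximized. Per parameter the penalties order as
(1/2)log₂N > log₂e > 1 for N ≥ 8, so MDL/BIC punish complexity hardest
at every sample size used here.

Because LL decomposes over families, `score_all` tabulates the joint
contingency tensor once (2ⁿ cells for binary variables) and reuses
marginalized family scores across structures; the full 543-structure
space on 4 nodes scores in milliseconds and the 29,281-structure space
on 5 nodes in well under a second.

## DAG space

Counts use the alternating-sign recurrence
f(n) = Σᵢ (−1)ⁱ⁺¹ C(n,i) 2^{i(n−i)} f(n−i), f(0) = 1, in exact integer
arithmetic (f(10) ≈ 4.2×10¹⁸ exceeds 53-bit float precision).
Enumeration iterates all 2^{n(n−1)} ordered-pair subsets in a fixed
bitmask order and filters by acyclicity — chosen for auditability over
clever generation; n = 5 (2²⁰ candidates) takes a few seconds. The
position in this sequence is a structure's canonical id, a repository
convention (nothing in the underlying experiment design fixes an
order); the empty graph is id 0. Equivalence keys are
(skeleton, v-structures); on 3 and 4 nodes the induced partition is
verified in the tests against an independent d-separation oracle
(moralized ancestral graph reachability). On 4 binary nodes the 543
structures fall into 185 score-equivalence classes.

## Synthetic gold standards

The generator reproduces the study conditions:

- **Structure.** A random ordered tree (node i's parent uniform on
  0..i−1) is refined by an add/remove Markov chain over *connected*
  acyclic digraphs: propose an ordered pair; remove the arc if the
  skeleton stays connected, add it if acyclicity is preserved. The
  proposal is symmetric, so the stationary distribution is uniform over
  connected DAGs; a chi-square test against the 18 connected 3-node
  DAGs checks this. The published pseudo-code for this step exists only
  as page images, so the move set follows the method's original
  description in the literature. Default chain length is 10·n² moves —
  several times the ~n² mixing scale observed in the uniformity test —
  and is configurable (`dag_steps`).
- **Parameters.** Random regime: each CPT row is uniform on the
  probability simplex, built from rᵢ − 1 sorted uniform cut points
  (for binary nodes, a single draw u gives (u, 1−u)). Low-entropy
  regime: every row is exactly (p, 1−p) with default p = 0.1
  (≈ 0.469 bits of entropy per draw), p applied to the first value of
  every row globally; a `flip_rng` option randomizes the orientation
  per row for sensitivity checks. Non-binary arities are supported by
  the types but the experiments, like the study they reproduce, are
  binary.
- **Data.** Ancestral sampling in a deterministic topological order;
  default sample sizes 1000/3000/5000 cases per gold standard.

Two generators are available behind one interface: numpy's PCG64
(default) and a 55-lag subtractive (ran3-style) generator provided for
its portability properties. Streams from the original study are not
reconstructible (no published seeds), so determinism under a declared
generator — identical seed, identical study, bit-for-bit — is the
contract, enforced by tests on files, not just values. A master seed is
expanded into independent sub-seeds (one per artifact: structure, CPTs,
each dataset) so any dataset can be regenerated in isolation.

What the generator does *not* emulate: real biological data with latent
confounders, missing entries, non-binary cardinalities, or sample sizes
far from the 10³–10⁴ range. Passing tests demonstrate the selection
behavior of the scores under the stated synthetic conditions, not
structure-learning performance on real systems.

## Envelopes, optima, distances

The lower envelope keeps, for each distinct k in a score table, the
optimal value and the tie set of structures within 1e-9 of it. The
global optimum reports all structures within 1e-9 of the best value —
score-equivalent (Markov-equivalent) structures always tie, so the tie
set is at least an equivalence class — with the lowest canonical id as
the designated representative ("the selected network"). The
gold-standard distance is log₂(gold/best) on the minimized positive
form of the metric; BIC is negated back to MDL first, so BIC and MDL
reports carry identical distances by construction. The distance is ≥ 0
whenever the optimum is global and 0 exactly when the gold standard's
class is selected.

The 1e-9 tie tolerance sits far above accumulated rounding
(~1e-11 absolute on scores of order 10⁴ bits) and far below the
smallest genuine score separations observed (~1e-3 bits), so tie sets
are insensitive to its exact value.

## Numerical and design choices

- Exact integer counts everywhere upstream of the log; no floating
  contingency tables.
- Parent-configuration rows are mixed-radix over parents sorted
  ascending with the highest-indexed parent varying fastest; the one
  convention is shared by the sampler, the scorer and the model file
  format.
- Degenerate inputs: deterministic columns give LL = 0 families;
  single-case datasets are legal; the empty file is a valid (empty)
  edge list but not a valid dataset (header required).
- Plots are scatter (k vs score) with the envelope, the optimum (red)
  and the gold standard (green); a TSV sidecar of plotted coordinates
  makes runs comparable without pixel diffs.

## Test problem sizes

The replicate studies in the test suite use 20 master seeds at N = 5000
on 4 binary nodes — enough replicates for a majority criterion on
qualitative claims while keeping the whole suite in tens of seconds.
The tests compute, among others: the empty-network selection rate of
MDL under low-entropy data (18/20 at the defaults), the rate at which
the selected minimum-MDL network differs from the gold structure, and
the AIC/MDL optimum-agreement rate. Two qualitative claims from the
literature did not replicate as majorities under these conditions and
their tests are left failing rather than weakened: AIC's optimum
usually lies in a strictly denser class than MDL's (its 1-bit-per-
parameter penalty is routinely beaten by the maximum of many spurious
fit gains), and exact equal-MDL/different-k coincidences at 1e-6
essentially never occur (the closest different-k score pairs observed
are ~1e-3 bits apart; such coincidences are a plotting-resolution
phenomenon, which the whole-bit-resolution degeneracy test does
confirm).

## Limitations

- Exhaustive analysis stops at n = 5 by design; nothing here addresses
  heuristic search, which is a separate (and, per the landscape
  degeneracy results, nontrivial) problem.
- The refined MDL with the Fisher-information functional-form term,
  Bayesian scores (BDe/CH), and classifier-accuracy evaluation of
  selected networks are out of scope.
- Chain-sampled structures are uniform only in the limit; at the
  default chain length the residual bias is below what the chi-square
  test can detect, but it is not exactly zero.
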