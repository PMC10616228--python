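# Methods

This note documents the models implemented by `pkst`, the choices made
where the mathematics or the protocol left room, and what the bundled
synthetic-data generator does and does not emulate.

## Problem spaces and the Tower of London generator

A problem space is a deterministic partial transition system (S, Ω, ·);
operation strings act by left-to-right composition, so the monoid laws
s·ε = s and (s·σ)·π = s·σπ hold by construction and are property-tested
on random strings.  The Tower of London generator enumerates the 36
states as six spatial arrangements × six color permutations on pegs of
capacity 3, 2, 1.  State identifiers are two-digit strings "ab":
`a` indexes the arrangement in the package's own order
(`TOL_ARRANGEMENTS`), `b` the color permutation (lexicographic over
R, G, B).  The coding is internal; a user-supplied relabeling can map it
onto any published numbering.  The designated goal state `"31"` is a
(2,1,0)-occupancy state: the two arrangement types with four legal moves
— (2,1,0) and (1,1,1) — are the only candidates compatible with a
35-problem goal space shrinking to 31 when one-move problems are
removed, and (2,1,0) is the one whose derived structures also match the
other published counts (11 problems with multiple minimal solutions;
242,498 knowledge states under the string comparability below).

Goal spaces are built as shortest-path spaces: a legal move from i to j
is kept iff d(j) = d(i) − 1 for the BFS distance d to the goal;
otherwise the move is redirected to the absorbing failure state f,
keeping its move label (determinism is preserved; at the parameter level
all failure entries of a state collapse to the single elementary pair
(i, f), matching the residual formulas).  `drop_one_move` removes the
problems of minimum length 1 from the domain, the usual practice when
one-move problems are uninformative.

## Subpath comparability: two readings

The subpath relation is sπ ⊑ tσ iff σ = απβ with t·α = s: the operation
substring must occur at a position where σ's trajectory passes through
s.  This *state-anchored* reading is the formal default (`match="state"`).

The package also implements a *move-sequence transfer* reading
(`match="string"`): π need only occur as a contiguous substring of σ,
regardless of where on the board it is executed.  Cognitively this
treats a memorized move sequence as a transferable skill; formally it is
a preorder rather than a partial order (distinct paths with equal
strings become mutually comparable).  On the nine-state running example
the two readings produce identical competence and knowledge spaces; on
the full ToL goal space they differ (525,265 vs 242,498 knowledge
states), and the string reading reproduces the published structure of
the full test, so the full-space fixtures and the acceptance script use
it.  Both modes are exposed everywhere a skill map is built.

## Knowledge-space derivation

The knowledge space is never obtained by enumerating the competence
space (which can be astronomically larger).  The atoms are the images
p(↓π) of single-path down-sets — in a shortest-path space these are the
domain states along the path (plus, under the string reading, the
initial states of any path whose string is a substring).  The space is
the union closure of the atoms together with ∅, computed by a single
fold: after processing atoms a₁…a_k the family holds every union of a
subset of them.  States are bit-masks over the lexicographically ordered
domain (the ordering is recorded in all serialized output); the
representation caps the domain at 62 problems.  Explicit
competence-space enumeration is guarded at 2²⁰ candidate subsets.  The
atom construction is verified against a brute-force image of all
down-sets on every fixture small enough to enumerate.

## The Markov solution process model

Each elementary transition (i, j) carries two rates: β_ij (solver knows
the relevant problems) and η_ij (solver does not), with failure entries
as row residuals so every transient row is a probability distribution.
The planning assumption decides the dispatch: MSP1 (pre-planning) looks
only at the posed problem (s0, g); MSP2 (interim planning) at the
current state's problem (i, g); MSP3 (mixed) requires both.  A current
state whose pair (i, g) is not a domain problem — a removed one-move
problem, or any state outside a restricted domain — counts as *not
known*: knowledge states are subsets of the domain by construction, and
the worked move-level likelihood values are reproduced only under this
convention.

## Synthetic-data generation

The generator draws, per transient state, both per-move error rates
from the same error level x: the careless-slip probability
β_if ~ Uniform(0, x] and the lucky-guess survival probability
1 − η_if ~ Uniform(0, x].  x is therefore the maximum per-move error of
either kind; x = .01 yields almost-noiseless data and x = .20 heavily
degraded data.  The off-failure entries of each row are independent
Uniform(0, 1) draws normalized to the row's remaining mass.  True
knowledge states are sampled i.i.d. from a random distribution over the
structure (independent Uniform(0, 1) weights, normalized); solution
processes are simulated move by move from the categorical rows until
goal or failure, termination being guaranteed by the goal-space
structure.

What this emulates: solvers with fixed, structure-consistent knowledge
states producing Markovian move sequences under a single parameter set
per condition.  What it does not: response times, learning or fatigue
across problems, individual parameter heterogeneity, non-Markovian
strategies, or states outside the assumed structure.  Passing tests
therefore demonstrate parameter-consistent recovery, not robustness to
model misspecification beyond the engine/generator mismatches the study
design itself crosses.

All randomness flows from one root seed through `numpy` `SeedSequence`
spawning, so any condition (and any single simulated subject) is
regenerable in isolation.

## Assessment engines

Both engines keep a likelihood over the knowledge states (uniform prior
unless one is supplied), select problems by half-split with ties broken
uniformly at random, administer each problem at most once by default
(repeats are available behind a flag), and renormalize after every
update; normalization is asserted to 1e−12, and arg-min/arg-max tie
sets use an absolute tolerance of 1e−12 for cross-platform
reproducibility.  Zero normalizing constants (an impossible response
under the model) raise rather than silently renormalize.  Weights are
renormalized after every move-update, which in practice controls
underflow even on the 242,498-state space.

The CMP consumes binary responses with per-problem careless/lucky rates
(β_q, η_q); the Bayesian and multiplicative forms are both implemented
and tested for equivalence under ζ_q,1 = (1−β_q)/η_q,
ζ_q,0 = (1−η_q)/β_q.  When the CMP is run inside the study harness on
dichotomized process data, its item parameters are derived from the
generating transition parameters as absorption probabilities of the
goal-space chain: β_q is the failure-absorption probability of the
β-rows started at q's initial state, η_q the goal-absorption
probability of the η-rows.  This is the exact dichotomous marginal under
pre-planning generation and a practical plug-in under the other two
assumptions.

Termination: the assessment stops once the maximal likelihood exceeds
the threshold p ∈ [.5, 1] (strictly greater), or when the domain is
exhausted; the record then retains all modal states and a tie-broken
single estimate.

## The study harness

Each simulated subject's full response pattern (one process per domain
problem) is generated in advance; every engine then replays the same
pattern, administering all problems.  The termination step m^w is
located afterwards as the first step whose maximal likelihood exceeds
the threshold.  The per-step accuracy and efficiency series (mean
Hamming distance D̄_m, mean entropy H̄_m in bits, proportion terminated
p_m) freeze each subject's likelihood at the termination step — the
only reading under which p_m is monotone — while the true-positive rate
compares the truth with the modal estimate after the *whole* pattern
(m = |Q_g|).  True states and their sampling distribution are redrawn
from a per-structure seed, so same-structure conditions of equal sample
size see identical truths.

Default problem sizes: the bundled study runs on the running-example
structure (11 states, 5 problems) with N = 155 subjects per condition —
small enough for the whole factorial design to run in seconds while
exhibiting the full qualitative pattern (near-perfect matched recovery
at x = .01, monotone D̄_m/H̄_m, CMP most noise-sensitive).  The
full-space structure (242,498 states, 31 problems) is derivable on
demand and accepted by the same harness; any user-supplied structure of
at most 62 problems can be plugged in.  The published 61-state structure
of the *reduced* ToL test is not bundled: its goal space is a
hand-picked subgraph whose exact edge set is not derivable from the
test's published description, so the harness substitutes the two
structures above.

## Known limitations

* Bit-mask structures cap the domain at 62 problems.
* The competence space is only enumerated explicitly up to the 2²⁰
  candidate-subset guard; beyond that only the knowledge space is
  available.
* `derive_item_params` is approximate for interim/mixed-planning
  generation (exact for pre-planning).
* The string comparability is a preorder; down-sets remain well defined,
  but antisymmetry-based reasoning applies only to the state-anchored
  mode.
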