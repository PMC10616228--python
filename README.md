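# pkst — procedural knowledge space theory

Adaptive assessment of problem-solving skill from *observed solution
processes*, not just right/wrong answers.

Neuropsychological planning tests such as the Tower of London (ToL) pose
problems inside a *problem space*: a finite set of board configurations
(problem states) connected by legal moves.  The ToL has 36 states, 108
directed moves, and 1260 distinct problems, yet a standard administration
uses a dozen fixed items and records only pass/fail.  This package
implements procedural knowledge space theory (PKST), which models what a
person can solve as a *knowledge state* — a subset of problems closed
under the structure of the space — and infers that state adaptively from
the sequence of moves the person actually makes.

## The model

A **problem space** is a triple (S, Ω, ·) of states, operations, and a
deterministic partial application map; a **problem** is a pair (s, t)
with t reachable from s.  A **goal space** adds absorbing goal and
failure states g, f; in a *shortest-path* goal space any move leaving
every minimum-length path to g enters f, so solving means producing a
minimal move sequence.  Each problem's minimum-length **solution paths**
are the skills that solve it (the skill map τ); paths are partially
ordered by the subpath relation ⊑ (knowing a path implies knowing its
subpaths).  Down-closed path sets are **competence states**, and the
problem function p(C) = {q : τ(q) ∩ C ≠ ∅} maps them to knowledge
states; the family 𝒦 = {p(C)} is a union-closed **knowledge space**,
computed here as the union closure of the atoms p(↓π).

The **Markov solution process model** (MSPM) turns this into a
likelihood for observed move sequences: each elementary transition
(i, j) has a rate β_ij when the solver knows the relevant problem(s) and
η_ij otherwise, with failure entries as row residuals
β_if = 1 − Σ_{j≠f} β_ij.  Which rate applies is set by a planning
assumption — pre-planning (MSP1: dispatch on the posed problem s0),
interim planning (MSP2: dispatch on the current state i), or mixed
planning (MSP3: both).

Assessment keeps a likelihood ℒ over 𝒦, starts uniform, selects each
next problem by the half-split rule (minimize |2·ℒ(𝒦_q) − 1|), and
updates Bayesianly — once per response in the classical continuous
Markov procedure (CMP), or once per *move* in the MSP-based procedures:

    ℒ(K) ∝ P(s_{n+1} | s_n, s_0, K) · ℒ(K)

stopping when some state exceeds a threshold p.  The move-level update
is equivalent to a multiplicative rule with ζ = β_ij/η_ij
(ζ = η_if/β_if for failure entries) whenever β_ij > η_ij and
η_if > β_if.

## Worked example

The nine-state running example: a solver whose knowledge state is
{s1, s3, s4, s7, s8} is assessed by the MSP-based procedure under mixed
planning, feeding it the two observed solution processes
(s4, s6, s8, s9) and (s1, s3, s5, s7, s8, s9):

```python
import numpy as np
from pkst import run_assessment
from pkst.fixtures import fig2_goal_space, ktol_structure, table4_params
from pkst.mspm import SolutionProcess
from pkst.spaces import Problem

gs = fig2_goal_space()          # goal space, goal s9, 5-problem domain
ks = ktol_structure()           # its 11-state knowledge space
params = table4_params()        # β/η rates per elementary move
processes = {
    Problem("s4", "s9"): SolutionProcess(Problem("s4", "s9"),
                                         ("s4", "s6", "s8", "s9")),
    Problem("s1", "s9"): SolutionProcess(Problem("s1", "s9"),
                                         ("s1", "s3", "s5", "s7", "s8", "s9")),
}
record = run_assessment(
    ks, gs, lambda q: processes[q], "msp3",
    trans_params=params, threshold=0.5, rng=np.random.default_rng(7),
)
print("problems asked:   ", [q.initial for q in record.administered])
print("recovered state:  ", sorted(q.initial for q in record.estimate))
print("final likelihood:  %.2f" % record.final.weights.max())
```

```
problems asked:    ['s4', 's1']
recovered state:   ['s1', 's3', 's4', 's7', 's8']
final likelihood:  0.92
```

Two problems suffice: the second process contains the solution paths of
s3 and s7 as subpaths, so their mastery is inferred without asking.  The
CMP on the same solver's pass/fail responses needs a third question
(`tests/test_assessment.py` walks through both).

## Command line

A thin `pkst` CLI wraps the library: `pkst space build-tol`,
`pkst space goalspace --goal 31 --drop-one-move`, `pkst derive kspace`,
`pkst sim params|processes`, `pkst assess`, `pkst study run`,
`pkst fixture <name>`.  All formats are plain text (JSON / CSV / JSONL /
YAML); every stochastic subcommand takes `--seed` and is byte-for-byte
reproducible.

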