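"""Problem spaces, goal spaces and solution paths.

A *problem space* is a finite deterministic labeled transition system
``(S, Ω, ·)``: a set of problem states, a set of operations, and a partial
application map ``(state, operation) -> state``.  Operation strings act by
left-to-right composition, so ``s · ε = s`` and ``(s·σ)·π = s·σπ`` hold by
construction.  A *problem* is an ordered pair ``(initial, goal)`` of distinct
states with the goal reachable from the initial state.

A *goal space* is a problem space with two distinguished absorbing states,
the goal ``g`` and the failure state ``f``; every other state can reach
``g``.  The spaces used for the Tower of London are *shortest-path* goal
spaces: any move that leaves every minimum-length path to the goal enters
the failure state, so a problem is solved only by a minimum-length move
sequence.

The Tower of London (ToL) generator builds the classic three-ball,
three-peg puzzle with peg capacities 3, 2 and 1: six spatial arrangements
of the balls times six color permutations give 36 problem states, and the
six peg-to-peg moves give 108 directed legal moves.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "Problem",
    "SolutionPath",
    "ProblemSpace",
    "GoalSpace",
    "build_tol_space",
    "tol_state_contents",
    "enumerate_problems",
    "make_sp_goal_space",
    "enumerate_solution_paths",
    "is_subpath",
    "TOL_OPERATIONS",
    "TOL_INVERSE",
]


class Problem(NamedTuple):
    """An ordered pair of distinct problem states (initial, goal)."""

    initial: str
    goal: str


@dataclass(frozen=True, order=True)
class SolutionPath:
    """A start state together with a non-empty operation string.

    The path ``s π`` solves problem ``(s, t)`` when applying ``π`` to ``s``
    yields ``t``.  Operation strings are stored as tuples of operation
    labels; ``label`` renders the usual compact form, e.g. ``"s4:ABA"``.
    """

    start: str
    ops: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ops:
            raise ValueError("a solution path needs a non-empty operation string")

    @property
    def label(self) -> str:
        return f"{self.start}:{''.join(self.ops)}"

    def __len__(self) -> int:
        return len(self.ops)


def _as_ops(ops: str | Iterable[str]) -> tuple[str, ...]:
    """Accept either a string of single-character labels or an iterable."""
    if isinstance(ops, str):
        return tuple(ops)
    return tuple(ops)


@dataclass(frozen=True)
class ProblemSpace:
    """Finite deterministic partial transition system over problem states."""

    states: frozenset[str]
    operations: frozenset[str]
    transitions: Mapping[tuple[str, str], str] = field(hash=False)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "ProblemSpace":
        """Build a space from ``(state, operation, successor)`` triples."""
        trans: dict[tuple[str, str], str] = {}
        states: set[str] = set()
        ops: set[str] = set()
        for s, w, t in edges:
            key = (s, w)
            if key in trans and trans[key] != t:
                raise ValueError(f"non-deterministic operation {w!r} at state {s!r}")
            trans[key] = t
            states.update((s, t))
            ops.add(w)
        return cls(frozenset(states), frozenset(ops), trans)

    def apply(self, state: str, ops: str | Iterable[str]) -> str | None:
        """Apply an operation string left to right; None when undefined."""
        cur = state
        for w in _as_ops(ops):
            nxt = self.transitions.get((cur, w))
            if nxt is None:
                return None
            cur = nxt
        return cur

    def successors(self, state: str) -> dict[str, str]:
        """Mapping operation -> successor for the legal moves at ``state``."""
        return {
            w: t for (s, w), t in self.transitions.items() if s == state
        }

    def legal_moves(self, state: str) -> list[str]:
        return sorted(self.successors(state))

    def edges(self) -> Iterator[tuple[str, str, str]]:
        for (s, w), t in self.transitions.items():
            yield s, w, t

    def reachable_from(self, state: str) -> set[str]:
        seen = {state}
        frontier = deque([state])
        succ_index: dict[str, list[str]] = {}
        for (s, _), t in self.transitions.items():
            succ_index.setdefault(s, []).append(t)
        while frontier:
            u = frontier.popleft()
            for v in succ_index.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    frontier.append(v)
        return seen


@dataclass(frozen=True)
class GoalSpace:
    """A problem space with absorbing goal and failure states.

    ``space`` already contains the failure state and the absorbing
    self-loops required by the definition; ``distance`` holds the
    minimum number of moves from each state to the goal *in the base
    space* (used by the shortest-path construction and by path
    enumeration).  ``domain`` lists the problems ``(s, goal)`` the goal
    space poses, in lexicographic order of the initial state.
    """

    space: ProblemSpace
    goal: str
    failure: str
    domain: tuple[Problem, ...]
    distance: Mapping[str, int] = field(hash=False)

    @property
    def problem_states(self) -> frozenset[str]:
        return self.space.states - {self.failure}

    def elementary_pairs(self) -> set[tuple[str, str]]:
        """All elementary problems (i, j), one failure pair per state.

        Every transient state gets a failure pair even when no single move
        of the underlying space reaches the failure state: the residual
        probabilities β_if/η_if are defined for every transient row.
        """
        pairs = set()
        for s, _, t in self.space.edges():
            pairs.add((s, t))
        for s in self.space.states - {self.goal, self.failure}:
            pairs.add((s, self.failure))
        return pairs

    def min_length(self, problem: Problem) -> int:
        return self.distance[problem.initial]

    def restrict_domain(self, initials: Iterable[str]) -> "GoalSpace":
        """Keep only the problems whose initial state is listed.

        The transition structure is untouched; this mirrors working with a
        sub-domain such as the five-problem running example.
        """
        keep = set(initials)
        unknown = keep - {p.initial for p in self.domain}
        if unknown:
            raise ValueError(f"not domain problems: {sorted(unknown)}")
        dom = tuple(p for p in self.domain if p.initial in keep)
        return GoalSpace(self.space, self.goal, self.failure, dom, self.distance)


# --------------------------------------------------------------------------
# Tower of London generator
# --------------------------------------------------------------------------

_CAPACITIES = (3, 2, 1)
#: the six peg-to-peg moves; uppercase is the reverse of the lowercase move
TOL_OPERATIONS = ("a", "b", "c", "A", "B", "C")
TOL_INVERSE = {"a": "A", "b": "B", "c": "C", "A": "a", "B": "b", "C": "c"}
_MOVE_PEGS = {
    "a": (0, 1),  # left  -> center
    "b": (1, 2),  # center -> right
    "c": (0, 2),  # left  -> right
    "A": (1, 0),  # center -> left
    "B": (2, 1),  # right -> center
    "C": (2, 0),  # right -> left
}

#: spatial arrangements (occupancy of left, center, right peg), in the
#: package's own coding order.  Index 3 is the (2,1,0) arrangement: the one
#: whose states admit four legal moves and reproduce the published
#: structure counts when used as the goal ("state 31" of the standard
#: test).  Index 5, the (1,1,1) arrangement, is the other four-move type.
TOL_ARRANGEMENTS = (
    (3, 0, 0),
    (2, 0, 1),
    (2, 1, 0),
    (1, 2, 0),
    (1, 1, 1),
    (0, 2, 1),
)

#: color permutations (bottom-to-top filling order of the arrangement),
#: coded 1-6 in lexicographic order
TOL_COLORS = tuple(itertools.permutations("RGB"))


def _tol_state(arrangement: int, colors: int) -> tuple[tuple[str, ...], ...]:
    occ = TOL_ARRANGEMENTS[arrangement - 1]
    perm = TOL_COLORS[colors - 1]
    pegs = []
    k = 0
    for n in occ:
        pegs.append(tuple(perm[k : k + n]))
        k += n
    return tuple(pegs)


def tol_state_contents(state_id: str) -> tuple[tuple[str, ...], ...]:
    """Peg contents (bottom to top) for a ToL state id like ``"31"``."""
    if len(state_id) != 2 or not state_id.isdigit():
        raise ValueError(f"not a ToL state id: {state_id!r}")
    a, b = int(state_id[0]), int(state_id[1])
    if not (1 <= a <= 6 and 1 <= b <= 6):
        raise ValueError(f"not a ToL state id: {state_id!r}")
    return _tol_state(a, b)


def _tol_id(pegs: tuple[tuple[str, ...], ...]) -> str:
    occ = tuple(len(p) for p in pegs)
    perm = tuple(itertools.chain.from_iterable(pegs))
    return f"{TOL_ARRANGEMENTS.index(occ) + 1}{TOL_COLORS.index(perm) + 1}"


def build_tol_space() -> ProblemSpace:
    """The Tower of London move graph: 36 states, 108 directed moves.

    State ids are two-digit strings ``"ab"``: ``a`` is the spatial
    arrangement (1-6, see :data:`TOL_ARRANGEMENTS`) and ``b`` the color
    permutation (1-6, lexicographic over R, G, B).  A move is legal iff the
    source peg is non-empty and the target peg is below capacity; it moves
    the top ball.
    """
    edges = []
    for a in range(1, 7):
        for b in range(1, 7):
            pegs = _tol_state(a, b)
            for w, (i, j) in _MOVE_PEGS.items():
                if pegs[i] and len(pegs[j]) < _CAPACITIES[j]:
                    moved = [list(p) for p in pegs]
                    ball = moved[i].pop()
                    moved[j].append(ball)
                    target = tuple(tuple(p) for p in moved)
                    edges.append((_tol_id(pegs), w, _tol_id(target)))
    return ProblemSpace.from_edges(edges)


# --------------------------------------------------------------------------
# Problems and goal spaces
# --------------------------------------------------------------------------

def enumerate_problems(space: ProblemSpace) -> set[Problem]:
    """All ordered pairs (s, t), s != t, with t reachable from s."""
    out: set[Problem] = set()
    for s in space.states:
        for t in space.reachable_from(s):
            if t != s:
                out.add(Problem(s, t))
    return out


def _distances_to(space: ProblemSpace, goal: str) -> dict[str, int]:
    """Minimum move counts to ``goal`` (BFS on the reversed move graph)."""
    preds: dict[str, list[str]] = {}
    for s, _, t in space.edges():
        preds.setdefault(t, []).append(s)
    dist = {goal: 0}
    frontier = deque([goal])
    while frontier:
        u = frontier.popleft()
        for v in preds.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)
    return dist


def make_sp_goal_space(
    space: ProblemSpace,
    goal: str,
    drop_one_move: bool = False,
    failure: str = "f",
) -> GoalSpace:
    """Shortest-path goal space for ``goal``, with an added failure state.

    Every legal move that stays on some minimum-length path to the goal is
    kept; any other legal move transits to the absorbing failure state
    (keeping its move label).  The goal and failure states absorb every
    operation.  ``drop_one_move`` removes the problems solvable in a single
    move from the domain, as is customary when the one-move problems are
    considered too easy to be informative.
    """
    if goal not in space.states:
        raise ValueError(f"goal {goal!r} is not a state of the space")
    if failure in space.states:
        raise ValueError(f"failure label {failure!r} collides with a state")
    dist = _distances_to(space, goal)
    missing = space.states - dist.keys()
    if missing:
        raise ValueError(
            f"goal space condition GS2 violated: goal unreachable from {sorted(missing)}"
        )
    edges = []
    for s, w, t in space.edges():
        if s == goal:
            continue  # replaced by absorbing self-loops below
        if dist[t] == dist[s] - 1:
            edges.append((s, w, t))
        else:
            edges.append((s, w, failure))
    for w in sorted(space.operations):
        edges.append((goal, w, goal))
        edges.append((failure, w, failure))
    gspace = ProblemSpace.from_edges(edges)
    min_len = 2 if drop_one_move else 1
    domain = tuple(
        Problem(s, goal)
        for s in sorted(space.states)
        if s != goal and dist[s] >= min_len
    )
    return GoalSpace(gspace, goal, failure, domain, dist)


# --------------------------------------------------------------------------
# Solution paths and the subpath relation
# --------------------------------------------------------------------------

def enumerate_solution_paths(gs: GoalSpace) -> dict[Problem, frozenset[SolutionPath]]:
    """All minimum-length solving paths, grouped by domain problem.

    In a shortest-path goal space every solving path is minimum-length, so
    the enumeration walks the distance-decreasing moves only.  The returned
    mapping is the raw form of the skill map τ.
    """
    succ: dict[str, list[tuple[str, str]]] = {}
    for s, w, t in gs.space.edges():
        if t != gs.failure and s != gs.goal:
            succ.setdefault(s, []).append((w, t))

    cache: dict[str, list[tuple[str, ...]]] = {}

    def paths_from(s: str) -> list[tuple[str, ...]]:
        if s == gs.goal:
            return [()]
        if s not in cache:
            out = []
            for w, t in sorted(succ.get(s, ())):
                if gs.distance[t] == gs.distance[s] - 1:
                    out.extend((w,) + rest for rest in paths_from(t))
            cache[s] = out
        return cache[s]

    tau: dict[Problem, frozenset[SolutionPath]] = {}
    for prob in gs.domain:
        tau[prob] = frozenset(
            SolutionPath(prob.initial, ops) for ops in paths_from(prob.initial)
        )
        if not tau[prob]:
            raise ValueError(f"problem {prob} has no solving path")
    return tau


def is_subpath(
    p: SolutionPath,
    q: SolutionPath,
    space: ProblemSpace,
    match: str = "state",
) -> bool:
    """Whether ``p`` is a subpath of ``q`` (the ⊑ relation).

    ``p = sπ`` is a subpath of ``q = tσ`` when strings α, β exist with
    ``σ = απβ`` and ``t·α = s``: π occurs as a contiguous substring of σ at
    a position where the trajectory of σ passes through s.  With
    ``match="string"`` the start-state anchoring ``t·α = s`` is waived and
    only the substring occurrence of the operation string is required —
    the *move-sequence transfer* reading, under which knowing a sequence of
    moves counts regardless of where on the board it was learned.

    The relation is reflexive and transitive; with ``match="string"`` it is
    a preorder (distinct paths sharing an operation string become mutually
    comparable).
    """
    n, m = len(p.ops), len(q.ops)
    if n > m:
        return False
    if match == "string":
        po, qo = "".join(p.ops), "".join(q.ops)
        return po in qo
    if match != "state":
        raise ValueError(f"unknown match mode {match!r}")
    cur = q.start
    for k in range(m - n + 1):
        if cur is None:
            return False
        if cur == p.start and q.ops[k : k + n] == p.ops:
            return True
        cur = space.apply(cur, (q.ops[k],))
    return False
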