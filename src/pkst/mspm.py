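"""The Markov solution process model (MSPM).

The solution behavior of a problem solver in knowledge state ``K`` who
attempts problem ``(s0, g)`` in a goal space is a Markov chain over the
problem states, absorbed at the goal or the failure state.  The model
parameterizes each elementary transition ``(i, j)`` with two rates:
``β_ij`` used when the solver *knows* the relevant problem(s) and ``η_ij``
used when she does not.  For each transient state the failure entries are
the row residuals ``β_if = 1 - Σ_{j≠f} β_ij`` and ``η_if = 1 - Σ_{j≠f} η_ij``,
so that every row is a probability distribution.

Which rate applies is decided by the planning assumption:

=========  ======================================  ===========================
tag        β applies iff                           interpretation
=========  ======================================  ===========================
``msp1``   ``(s0, g) ∈ K``                         pre-planning
``msp2``   ``(i, g) ∈ K``                          interim planning
``msp3``   ``(s0, g) ∈ K`` and ``(i, g) ∈ K``      mixed planning
=========  ======================================  ===========================

A current state ``i`` for which ``(i, g)`` is not a domain problem (the
goal's direct neighbors when one-move problems are dropped, or states
outside a reduced domain) counts as *not* belonging to ``K``: knowledge
states are subsets of the domain by construction.

This module also hosts the synthetic-data generators used by the
simulation harness: uniform-interval transition-parameter draws,
knowledge-state sampling under a random distribution, and the move-by-move
process simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .knowledge import KnowledgeStructure
from .spaces import GoalSpace, Problem

__all__ = [
    "PlanningAssumption",
    "TransitionParams",
    "SolutionProcess",
    "uses_beta",
    "transition_prob",
    "simulate_process",
    "generate_params",
    "sample_states",
    "dichotomize",
]

PlanningAssumption = Literal["msp1", "msp2", "msp3"]

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class SolutionProcess:
    """The observed state sequence of one problem attempt."""

    problem: Problem
    visited: tuple[str, ...]

    @property
    def terminal(self) -> str:
        return self.visited[-1]

    def moves(self) -> list[tuple[str, str]]:
        return list(zip(self.visited, self.visited[1:]))


@dataclass(frozen=True)
class TransitionParams:
    """β/η rates per elementary transition of a goal space.

    ``beta`` and ``eta`` map elementary pairs ``(i, j)`` — including the
    failure pair ``(i, f)`` — to probabilities.  Rows of transient states
    sum to one; the absorbing goal and failure rows are the identity.
    """

    goal: str
    failure: str
    beta: Mapping[tuple[str, str], float] = field(hash=False)
    eta: Mapping[tuple[str, str], float] = field(hash=False)

    def __post_init__(self) -> None:
        for name, table in (("beta", self.beta), ("eta", self.eta)):
            rows: dict[str, float] = {}
            for (i, _), p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{i}] entry {p} outside [0, 1]")
                rows[i] = rows.get(i, 0.0) + p
            for i, tot in rows.items():
                if i in (self.goal, self.failure):
                    continue
                if abs(tot - 1.0) > _ROW_TOL:
                    raise ValueError(f"{name} row of {i!r} sums to {tot}, not 1")

    @classmethod
    def from_edge_table(
        cls,
        gs: GoalSpace,
        rows: Iterable[tuple[str, str, float, float]],
    ) -> "TransitionParams":
        """Build from ``(i, j, beta_ij, eta_ij)`` rows without failure entries.

        Failure entries are filled in as the row residuals, the standard
        way a printed parameter table omits them.
        """
        beta: dict[tuple[str, str], float] = {}
        eta: dict[tuple[str, str], float] = {}
        pairs = gs.elementary_pairs()
        for i, j, b, e in rows:
            if (i, j) not in pairs:
                raise ValueError(f"({i!r}, {j!r}) is not an elementary transition")
            beta[(i, j)] = float(b)
            eta[(i, j)] = float(e)
        states = {i for (i, _) in pairs} - {gs.goal, gs.failure}
        for i in states:
            bsum = sum(p for (s, t), p in beta.items() if s == i and t != gs.failure)
            esum = sum(p for (s, t), p in eta.items() if s == i and t != gs.failure)
            if bsum > 1 + _ROW_TOL or esum > 1 + _ROW_TOL:
                raise ValueError(f"row of {i!r} exceeds 1 before the failure residual")
            beta[(i, gs.failure)] = max(0.0, 1.0 - bsum)
            eta[(i, gs.failure)] = max(0.0, 1.0 - esum)
        beta[(gs.goal, gs.goal)] = 1.0
        eta[(gs.goal, gs.goal)] = 1.0
        beta[(gs.failure, gs.failure)] = 1.0
        eta[(gs.failure, gs.failure)] = 1.0
        return cls(gs.goal, gs.failure, beta, eta)

    def row(self, i: str, which: str) -> dict[str, float]:
        table = self.beta if which == "beta" else self.eta
        return {j: p for (s, j), p in table.items() if s == i}

    def is_multiplicative(self) -> bool:
        """Theorem condition: β_ij > η_ij for j ≠ f, and η_if > β_if."""
        for (i, j), b in self.beta.items():
            if i in (self.goal, self.failure):
                continue
            e = self.eta[(i, j)]
            if j == self.failure:
                if not e > b:
                    return False
            elif not b > e:
                return False
        return True


def _knows(i: str, K: frozenset[str], domain_initials: frozenset[str]) -> bool:
    return i in domain_initials and i in K


def uses_beta(
    assumption: PlanningAssumption,
    s0_known: bool,
    i_known: bool,
) -> bool:
    """The β/η dispatch of the three planning assumptions."""
    if assumption == "msp1":
        return s0_known
    if assumption == "msp2":
        return i_known
    if assumption == "msp3":
        return s0_known and i_known
    raise ValueError(f"unknown planning assumption {assumption!r}")


def transition_prob(
    i: str,
    j: str,
    s0: str,
    K: Iterable[str],
    params: TransitionParams,
    assumption: PlanningAssumption,
    gs: GoalSpace,
) -> float:
    """P(j | i, s0, K) under the given planning assumption.

    ``K`` is the knowledge state as the set of initial states of its
    problems (all problems of a goal space share the goal).
    """
    if (i, j) not in params.beta:
        raise ValueError(f"({i!r}, {j!r}) is not an elementary transition")
    Kset = frozenset(K)
    dom = frozenset(p.initial for p in gs.domain)
    if uses_beta(assumption, _knows(s0, Kset, dom), _knows(i, Kset, dom)):
        return params.beta[(i, j)]
    return params.eta[(i, j)]


def simulate_process(
    q: Problem,
    K: Iterable[str],
    params: TransitionParams,
    assumption: PlanningAssumption,
    gs: GoalSpace,
    rng: np.random.Generator,
) -> SolutionProcess:
    """Sample one solution process, move by move, until goal or failure."""
    if q not in gs.domain:
        raise ValueError(f"{q} is not a domain problem")
    Kset = frozenset(K)
    dom = frozenset(p.initial for p in gs.domain)
    s0_known = _knows(q.initial, Kset, dom)
    visited = [q.initial]
    cur = q.initial
    while cur not in (gs.goal, gs.failure):
        which = (
            "beta"
            if uses_beta(assumption, s0_known, _knows(cur, Kset, dom))
            else "eta"
        )
        row = params.row(cur, which)
        targets = sorted(row)
        probs = np.array([row[t] for t in targets])
        cur = targets[rng.choice(len(targets), p=probs / probs.sum())]
        visited.append(cur)
    return SolutionProcess(q, tuple(visited))


def generate_params(
    gs: GoalSpace,
    x: float,
    rng: np.random.Generator,
) -> TransitionParams:
    """Random transition parameters at error level ``x``.

    ``x`` bounds both per-move error rates: per transient state ``i`` the
    careless-slip probability is drawn ``β_if ~ Uniform(0, x]`` and the
    lucky-guess survival probability ``1 − η_if ~ Uniform(0, x]`` (so
    ``η_if ∈ [1 − x, 1)``: a solver who knows no path fails a move with
    probability at least ``1 − x``).  The remaining row entries are drawn
    Uniform(0, 1) and normalized so each row sums to one (off-failure mass
    ``1 − β_if`` resp. ``1 − η_if``).
    """
    if not 0.0 < x < 1.0:
        raise ValueError(f"error level x={x} outside (0, 1)")
    beta: dict[tuple[str, str], float] = {}
    eta: dict[tuple[str, str], float] = {}
    transients = sorted(gs.space.states - {gs.goal, gs.failure})
    for i in transients:
        succs = sorted(
            {t for (s, _), t in gs.space.transitions.items() if s == i and t != gs.failure}
        )
        b_f = x * (1.0 - float(rng.uniform()))  # Uniform(0, x]
        e_f = 1.0 - x * (1.0 - float(rng.uniform()))  # 1 - Uniform(0, x]
        bw = rng.uniform(size=len(succs))
        ew = rng.uniform(size=len(succs))
        bw = bw / bw.sum() * (1.0 - b_f)
        ew = ew / ew.sum() * (1.0 - e_f)
        for t, b, e in zip(succs, bw, ew):
            beta[(i, t)] = float(b)
            eta[(i, t)] = float(e)
        beta[(i, gs.failure)] = b_f
        eta[(i, gs.failure)] = e_f
    for s in (gs.goal, gs.failure):
        beta[(s, s)] = 1.0
        eta[(s, s)] = 1.0
    return TransitionParams(gs.goal, gs.failure, beta, eta)


def sample_states(
    ks: KnowledgeStructure,
    n: int,
    rng: np.random.Generator,
) -> tuple[list[frozenset[Problem]], np.ndarray]:
    """Sample ``n`` true states i.i.d. from a random distribution over ks.

    A weight is drawn Uniform(0, 1) per state and normalized; the returned
    pair is (sampled states, the distribution π_K itself).
    """
    if len(ks) == 0:
        raise ValueError("empty knowledge structure")
    weights = rng.uniform(size=len(ks))
    weights = weights / weights.sum()
    idx = rng.choice(len(ks), size=n, p=weights)
    states = [ks.state_set(int(ks.masks[i])) for i in idx]
    return states, weights


def dichotomize(sp: SolutionProcess, failure: str = "f") -> int:
    """1 if the process ended at the goal, 0 at the failure state."""
    if sp.terminal == sp.problem.goal:
        return 1
    if sp.terminal == failure:
        return 0
    raise ValueError(
        f"process for {sp.problem} did not terminate (last state {sp.terminal!r})"
    )
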