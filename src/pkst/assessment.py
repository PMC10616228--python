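"""Adaptive assessment engines.

Two families of procedures over a knowledge structure:

* the **continuous Markov procedure** (CMP) on dichotomous responses —
  half-split question selection, Bayesian (or equivalent multiplicative)
  likelihood updating with per-problem careless-error and lucky-guess
  rates, and a maximum-likelihood termination threshold;
* the **MSP-based procedures** on full solution processes — the same
  outer loop, but the likelihood is updated once per observed *move*
  using the Markov solution process model's transition probabilities
  under a planning assumption (``msp1``, ``msp2`` or ``msp3``).

Both keep a likelihood distribution over the knowledge states, start from
the uniform distribution, and stop as soon as some state's likelihood
exceeds the threshold ``p ∈ (.5, 1]`` (or the problem domain is
exhausted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _shannon

from .knowledge import KnowledgeStructure
from .mspm import PlanningAssumption, SolutionProcess, TransitionParams, uses_beta
from .spaces import GoalSpace, Problem

__all__ = [
    "Likelihood",
    "ItemParams",
    "StepRecord",
    "AssessmentRecord",
    "half_split_select",
    "cmp_update",
    "multiplicative_update",
    "msp_update",
    "derive_item_params",
    "run_assessment",
]

#: absolute tolerance for arg-min/arg-max tie sets
TIE_TOL = 1e-12
_NORM_TOL = 1e-12


@dataclass(frozen=True)
class Likelihood:
    """A probability distribution over the states of a structure."""

    structure: KnowledgeStructure
    weights: np.ndarray = field(hash=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.structure),):
            raise ValueError("weights must align with the structure")
        if (w < 0).any():
            raise ValueError("negative likelihood weight")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, structure: KnowledgeStructure) -> "Likelihood":
        n = len(structure)
        return cls(structure, np.full(n, 1.0 / n))

    def mass(self, q: Problem) -> float:
        """L(K_q): total likelihood of the states containing q."""
        return float(self.weights[self.structure.membership(q)].sum())

    def entropy_bits(self) -> float:
        return float(_shannon(self.weights, base=2))

    def modal_indices(self) -> np.ndarray:
        top = self.weights.max()
        return np.flatnonzero(self.weights >= top - TIE_TOL)

    def modal_states(self) -> list[frozenset[Problem]]:
        return [
            self.structure.state_set(int(self.structure.masks[i]))
            for i in self.modal_indices()
        ]

    def _renormalized(self, w: np.ndarray) -> "Likelihood":
        z = w.sum()
        if z <= 0:
            raise ZeroDivisionError("all-zero posterior: responses are impossible")
        return Likelihood(self.structure, w / z)


@dataclass(frozen=True)
class ItemParams:
    """Careless-error β_q and lucky-guess η_q per problem (keyed by initial state)."""

    beta: Mapping[str, float] = field(hash=False)
    eta: Mapping[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        for name, table in (("beta", self.beta), ("eta", self.eta)):
            for q, v in table.items():
                if not 0.0 < v < 1.0:
                    raise ValueError(f"{name}[{q!r}] = {v} outside (0, 1)")

    def zetas(self, q: str) -> tuple[float, float]:
        """(ζ_q,1, ζ_q,0) making the multiplicative rule match Bayes."""
        b, e = self.beta[q], self.eta[q]
        return (1.0 - b) / e, (1.0 - e) / b


def half_split_select(
    L: Likelihood,
    available: Iterable[Problem],
    rng: np.random.Generator,
) -> Problem:
    """The half-split questioning rule.

    Returns a problem minimizing ``|2·L(K_q) − 1|`` over the available
    problems; ties (within :data:`TIE_TOL`) are broken uniformly at
    random.
    """
    avail = sorted(set(available))
    if not avail:
        raise ValueError("no problems available for selection")
    scores = np.array([abs(2.0 * L.mass(q) - 1.0) for q in avail])
    best = scores.min()
    tied = np.flatnonzero(scores <= best + TIE_TOL)
    return avail[int(tied[int(rng.integers(len(tied)))])]


def cmp_update(
    L: Likelihood,
    q: Problem,
    r: int,
    ip: ItemParams,
) -> Likelihood:
    """Bayesian update of the likelihood after a dichotomous response.

    The response rule: P(r|K) is β_q / 1−η_q / 1−β_q / η_q according to
    whether the response is incorrect/correct and q is in K or not.
    """
    if r not in (0, 1):
        raise ValueError(f"response must be 0 or 1, got {r!r}")
    b, e = ip.beta[q.initial], ip.eta[q.initial]
    inK = L.structure.membership(q)
    if r == 1:
        p_resp = np.where(inK, 1.0 - b, e)
    else:
        p_resp = np.where(inK, b, 1.0 - e)
    return L._renormalized(p_resp * L.weights)


def multiplicative_update(
    L: Likelihood,
    q: Problem,
    r: int,
    zeta1: float,
    zeta0: float,
) -> Likelihood:
    """The multiplicative updating rule with weights ζ_q,1 and ζ_q,0.

    A correct response multiplies the states containing q by ζ_q,1, an
    incorrect one multiplies the states *not* containing q by ζ_q,0;
    everything else is left alone before renormalization.  With
    ζ_q,1 = (1−β_q)/η_q and ζ_q,0 = (1−η_q)/β_q it coincides with
    :func:`cmp_update`.
    """
    inK = L.structure.membership(q)
    if r == 1:
        mult = np.where(inK, zeta1, 1.0)
    else:
        mult = np.where(inK, 1.0, zeta0)
    return L._renormalized(mult * L.weights)


def _membership_or_none(
    structure: KnowledgeStructure, state: str, gs: GoalSpace
) -> np.ndarray:
    """Membership vector of problem (state, g); all-False off the domain."""
    prob = Problem(state, gs.goal)
    if prob in structure.domain:
        return structure.membership(prob)
    return np.zeros(len(structure), dtype=bool)


def msp_update(
    L: Likelihood,
    s0: str,
    i: str,
    j: str,
    params: TransitionParams,
    assumption: PlanningAssumption,
    gs: GoalSpace,
) -> Likelihood:
    """One move-level Bayesian update of the MSP-based procedure.

    The posterior is proportional to ``P(j | i, s0, K) · prior(K)`` where
    the transition probability is β_ij or η_ij per the planning
    assumption's dispatch, evaluated for every knowledge state at once.
    """
    if (i, j) not in params.beta:
        raise ValueError(f"({i!r}, {j!r}) is not an elementary transition")
    s0_in = _membership_or_none(L.structure, s0, gs)
    i_in = _membership_or_none(L.structure, i, gs)
    if assumption == "msp1":
        use_b = s0_in
    elif assumption == "msp2":
        use_b = i_in
    elif assumption == "msp3":
        use_b = s0_in & i_in
    else:
        raise ValueError(f"unknown planning assumption {assumption!r}")
    p = np.where(use_b, params.beta[(i, j)], params.eta[(i, j)])
    return L._renormalized(p * L.weights)


def derive_item_params(gs: GoalSpace, params: TransitionParams) -> ItemParams:
    """Dichotomous item parameters implied by the transition parameters.

    For each domain problem the careless-error rate is the probability
    that the goal-space chain run on the β rows is absorbed at the failure
    state, and the lucky-guess rate is the probability that the chain run
    on the η rows is absorbed at the goal.  This is the exact marginal
    under pre-planning generation and a practical plug-in otherwise.
    """
    transients = sorted(gs.space.states - {gs.goal, gs.failure})
    idx = {s: k for k, s in enumerate(transients)}

    def goal_absorption(which: str) -> dict[str, float]:
        n = len(transients)
        A = np.eye(n)
        b = np.zeros(n)
        for s in transients:
            row = params.row(s, which)
            for t, p in row.items():
                if t == gs.goal:
                    b[idx[s]] += p
                elif t != gs.failure:
                    A[idx[s], idx[t]] -= p
        r = np.linalg.solve(A, b)
        return {s: float(r[idx[s]]) for s in transients}

    r_beta = goal_absorption("beta")
    r_eta = goal_absorption("eta")
    eps = 1e-12
    beta_q = {
        p.initial: float(np.clip(1.0 - r_beta[p.initial], eps, 1 - eps))
        for p in gs.domain
    }
    eta_q = {
        p.initial: float(np.clip(r_eta[p.initial], eps, 1 - eps))
        for p in gs.domain
    }
    return ItemParams(beta_q, eta_q)


# --------------------------------------------------------------------------
# The assessment loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepRecord:
    """State of the assessment after one administered problem."""

    problem: Problem
    response: int | SolutionProcess
    max_likelihood: float
    modal_masks: tuple[int, ...]
    estimate: frozenset[Problem]
    entropy_bits: float
    weights: np.ndarray | None = None


@dataclass(frozen=True)
class AssessmentRecord:
    """Full account of one adaptive assessment."""

    steps: tuple[StepRecord, ...]
    final: Likelihood
    terminated: bool

    @property
    def n_questions(self) -> int:
        return len(self.steps)

    @property
    def administered(self) -> list[Problem]:
        return [s.problem for s in self.steps]

    @property
    def modal_states(self) -> list[frozenset[Problem]]:
        return self.final.modal_states()

    @property
    def estimate(self) -> frozenset[Problem]:
        return self.steps[-1].estimate

    def termination_step(self, threshold: float) -> int | None:
        """First step index (1-based) whose max likelihood exceeds the threshold."""
        for m, s in enumerate(self.steps, start=1):
            if s.max_likelihood > threshold:
                return m
        return None


ResponseProvider = Callable[[Problem], "int | Sequence[str] | SolutionProcess"]


def run_assessment(
    structure: KnowledgeStructure,
    gs: GoalSpace,
    provider: ResponseProvider,
    engine: str,
    *,
    item_params: ItemParams | None = None,
    trans_params: TransitionParams | None = None,
    threshold: float = 0.5,
    rng: np.random.Generator | None = None,
    prior: Likelihood | None = None,
    stop_early: bool = True,
    allow_repeat: bool = False,
    max_questions: int | None = None,
    keep_weights: bool = False,
) -> AssessmentRecord:
    """Run one adaptive assessment.

    ``engine`` is ``"cmp"`` (dichotomous responses, needs ``item_params``)
    or one of ``"msp1"``, ``"msp2"``, ``"msp3"`` (full solution processes,
    needs ``trans_params``).  The provider supplies, for each selected
    problem, a binary response (cmp) or the visited state sequence (msp*).
    Problems are administered at most once unless ``allow_repeat``; with
    ``stop_early`` unset the loop always exhausts the domain, which lets a
    study replay the whole response pattern and locate the termination
    step afterwards.
    """
    if engine not in ("cmp", "msp1", "msp2", "msp3"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "cmp" and item_params is None:
        raise ValueError("cmp engine needs item_params")
    if engine != "cmp" and trans_params is None:
        raise ValueError(f"{engine} engine needs trans_params")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError(f"termination threshold {threshold} outside [.5, 1]")
    if allow_repeat and not stop_early:
        raise ValueError("allow_repeat without stop_early would never terminate")
    rng = rng or np.random.default_rng()
    L = prior if prior is not None else Likelihood.uniform(structure)
    remaining = list(structure.domain)
    cap = max_questions if max_questions is not None else (
        len(structure.domain) if not allow_repeat else 10 * len(structure.domain)
    )
    steps: list[StepRecord] = []
    while remaining and len(steps) < cap:
        q = half_split_select(L, remaining, rng)
        if not allow_repeat:
            remaining.remove(q)
        answer = provider(q)
        if engine == "cmp":
            if isinstance(answer, SolutionProcess):
                raise TypeError("cmp engine expects a binary response")
            L = cmp_update(L, q, int(answer), item_params)
            response: int | SolutionProcess = int(answer)
        else:
            if isinstance(answer, SolutionProcess):
                process = answer
            else:
                process = SolutionProcess(q, tuple(answer))
            if process.visited[0] != q.initial:
                raise ValueError(
                    f"process starts at {process.visited[0]!r}, expected {q.initial!r}"
                )
            for i, j in process.moves():
                L = msp_update(L, q.initial, i, j, trans_params, engine, gs)
            response = process
        modal = L.modal_indices()
        pick = modal[int(rng.integers(len(modal)))]
        steps.append(
            StepRecord(
                problem=q,
                response=response,
                max_likelihood=float(L.weights.max()),
                modal_masks=tuple(int(structure.masks[i]) for i in modal),
                estimate=structure.state_set(int(structure.masks[pick])),
                entropy_bits=L.entropy_bits(),
                weights=L.weights.copy() if keep_weights else None,
            )
        )
        if stop_early and steps[-1].max_likelihood > threshold:
            return AssessmentRecord(tuple(steps), L, True)
    terminated = bool(steps and steps[-1].max_likelihood > threshold)
    return AssessmentRecord(tuple(steps), L, terminated)
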