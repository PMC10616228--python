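"""Performance metrics and the simulation-study harness.

Accuracy is measured by the average Hamming distance (size of the
symmetric difference between the true and the estimated knowledge state)
and by the true-positive rate (exact recovery at the end of the
assessment).  Efficiency is measured by the distribution of the number of
questions until the termination criterion, its mean, and the Shannon
entropy (bits) of the likelihood distribution at each step.

The study harness reproduces the factorial design of the comparison
study: generative planning assumption × knowledge structure × error level
× sample size, with every generated sample replayed through all four
engines (CMP on the dichotomized responses, MSP1/2/3 on the full
processes).  Indexes are reported at every question count ``m``; for
subjects whose termination criterion was met before ``m`` the likelihood
is frozen at the termination step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assessment import (
    AssessmentRecord,
    ItemParams,
    Likelihood,
    derive_item_params,
    run_assessment,
)
from .knowledge import KnowledgeStructure
from .mspm import (
    PlanningAssumption,
    SolutionProcess,
    TransitionParams,
    dichotomize,
    generate_params,
    sample_states,
    simulate_process,
)
from .spaces import GoalSpace, Problem

__all__ = [
    "StudyCondition",
    "MetricSeries",
    "hamming",
    "entropy",
    "tpr",
    "simulate_sample",
    "replay_sample",
    "run_study",
]


def hamming(K: Iterable[Problem], Khat: Iterable[Problem]) -> int:
    """|K Δ K̂|: the size of the symmetric difference of two states."""
    return len(frozenset(K) ^ frozenset(Khat))


def entropy(L: Likelihood) -> float:
    """Shannon entropy of a likelihood distribution, in bits (0·log0 = 0)."""
    return L.entropy_bits()


def tpr(estimates: Sequence[frozenset[Problem]], truths: Sequence[frozenset[Problem]]) -> float:
    """Proportion of subjects whose final estimate equals the true state."""
    if len(estimates) != len(truths):
        raise ValueError("estimates and truths must align")
    if not truths:
        raise ValueError("no subjects")
    return sum(e == t for e, t in zip(estimates, truths)) / len(truths)


@dataclass(frozen=True)
class StudyCondition:
    """One cell of the simulation design."""

    model: PlanningAssumption  # generative planning assumption
    structure: str  # key into the structures mapping passed to run_study
    error: float  # maximum careless-error level x
    n_subjects: int

    def __post_init__(self) -> None:
        if not 0.0 < self.error < 1.0:
            raise ValueError(f"error level {self.error} outside (0, 1)")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


@dataclass(frozen=True)
class MetricSeries:
    """Per-step and scalar performance indexes of one (condition, engine)."""

    engine: str
    steps: tuple[int, ...]  # question counts m = 1..|Q_g|
    mean_hamming: tuple[float, ...]  # D̄_m
    mean_entropy: tuple[float, ...]  # H̄_m
    prop_terminated: tuple[float, ...]  # p_m
    tpr: float
    mean_questions: float  # m̄ (termination step; |Q_g| when never reached)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"engine": self.engine, "m": m, "metric": name, "value": v}
            for name, series in (
                ("mean_hamming", self.mean_hamming),
                ("mean_entropy", self.mean_entropy),
                ("prop_terminated", self.prop_terminated),
            )
            for m, v in zip(self.steps, series)
        ]
        rows.append({"engine": self.engine, "m": None, "metric": "tpr", "value": self.tpr})
        rows.append(
            {"engine": self.engine, "m": None, "metric": "mean_questions", "value": self.mean_questions}
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulatedSubject:
    """True state plus the pre-generated response pattern (one process per problem)."""

    true_state: frozenset[Problem]
    processes: Mapping[Problem, SolutionProcess] = field(hash=False)


def simulate_sample(
    gs: GoalSpace,
    structure: KnowledgeStructure,
    model: PlanningAssumption,
    params: TransitionParams,
    true_states: Sequence[frozenset[Problem]],
    rng: np.random.Generator,
) -> list[SimulatedSubject]:
    """Generate the full response pattern of every subject in advance.

    Each subject attempts every domain problem once; the solution process
    is simulated move by move under the generative planning assumption.
    """
    subjects = []
    for K in true_states:
        initials = frozenset(q.initial for q in K)
        processes = {
            q: simulate_process(q, initials, params, model, gs, rng)
            for q in structure.domain
        }
        subjects.append(SimulatedSubject(K, processes))
    return subjects


def _scripted_provider(subject: SimulatedSubject, engine: str, failure: str):
    if engine == "cmp":
        return lambda q: dichotomize(subject.processes[q], failure)
    return lambda q: subject.processes[q]


def replay_sample(
    gs: GoalSpace,
    structure: KnowledgeStructure,
    subjects: Sequence[SimulatedSubject],
    engine: str,
    params: TransitionParams,
    rng: np.random.Generator,
    threshold: float = 0.5,
    item_params: ItemParams | None = None,
) -> MetricSeries:
    """Replay a stored sample through one engine and compute all indexes.

    Every assessment runs to domain exhaustion; the termination step is
    located afterwards.  The per-step accuracy/efficiency series use the
    likelihood frozen at the termination step, while the true-positive
    rate compares the truth with the estimate after the whole response
    pattern (m = |Q_g|), mirroring the study protocol.  The CMP engine
    consumes dichotomized responses with item parameters derived from the
    transition parameters unless explicit ones are supplied.
    """
    if engine == "cmp" and item_params is None:
        item_params = derive_item_params(gs, params)
    n_q = len(structure.domain)
    n = len(subjects)
    ham = np.zeros((n, n_q))
    ent = np.zeros((n, n_q))
    term = np.zeros((n, n_q), dtype=bool)
    final_est: list[frozenset[Problem]] = []
    m_term = np.zeros(n)
    for w, subj in enumerate(subjects):
        record = run_assessment(
            structure,
            gs,
            _scripted_provider(subj, engine, gs.failure),
            engine,
            item_params=item_params,
            trans_params=params,
            threshold=threshold,
            rng=rng,
            stop_early=False,
        )
        t = record.termination_step(threshold)
        m_term[w] = t if t is not None else n_q
        frozen_at = (t or n_q) - 1
        for m in range(n_q):
            step = record.steps[min(m, frozen_at)]
            ham[w, m] = hamming(subj.true_state, step.estimate)
            ent[w, m] = step.entropy_bits
            term[w, m] = t is not None and (m + 1) >= t
        final_est.append(record.steps[-1].estimate)
    truths = [s.true_state for s in subjects]
    return MetricSeries(
        engine=engine,
        steps=tuple(range(1, n_q + 1)),
        mean_hamming=tuple(ham.mean(axis=0)),
        mean_entropy=tuple(ent.mean(axis=0)),
        prop_terminated=tuple(term.mean(axis=0)),
        tpr=tpr(final_est, truths),
        mean_questions=float(m_term.mean()),
    )


def run_study(
    conditions: Sequence[StudyCondition],
    goal_spaces: Mapping[str, GoalSpace],
    structures: Mapping[str, KnowledgeStructure],
    seed: int,
    engines: Sequence[str] = ("cmp", "msp1", "msp2", "msp3"),
    threshold: float = 0.5,
    return_manifest: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Run the factorial simulation study; returns a tidy metric table.

    The random state distribution and the drawn true states are shared
    across all conditions using the same structure (they are re-drawn from
    a per-structure seed, so same-structure conditions of equal sample
    size see identical truths), matching the study protocol.  Everything
    is reproducible from ``seed``; ``return_manifest`` additionally
    returns the seeds and the per-condition true states.
    """
    root = np.random.SeedSequence(seed)
    struct_seeds = {
        name: s for name, s in zip(sorted(structures), root.spawn(len(structures)))
    }
    frames = []
    manifest: dict = {"seed": seed, "conditions": []}
    for c_idx, cond in enumerate(conditions):
        gs = goal_spaces[cond.structure]
        structure = structures[cond.structure]
        state_rng = np.random.default_rng(struct_seeds[cond.structure])
        true_states, _ = sample_states(structure, cond.n_subjects, state_rng)
        cond_seq = np.random.SeedSequence([seed, c_idx])
        gen_rng, sim_rng, assess_rng = (
            np.random.default_rng(s) for s in cond_seq.spawn(3)
        )
        params = generate_params(gs, cond.error, gen_rng)
        subjects = simulate_sample(gs, structure, cond.model, params, true_states, sim_rng)
        manifest["conditions"].append(
            {
                "condition": c_idx + 1,
                "model": cond.model,
                "structure": cond.structure,
                "error": cond.error,
                "n_subjects": cond.n_subjects,
                "true_states": [
                    tuple(sorted(q.initial for q in K)) for K in true_states
                ],
            }
        )
        for engine in engines:
            series = replay_sample(
                gs, structure, subjects, engine, params, assess_rng, threshold
            )
            frame = series.to_frame()
            frame.insert(0, "condition", c_idx + 1)
            frame.insert(1, "model", cond.model)
            frame.insert(2, "structure", cond.structure)
            frame.insert(3, "error", cond.error)
            frame.insert(4, "n_subjects", cond.n_subjects)
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    if return_manifest:
        return table, manifest
    return table
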