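"""Bundled reference objects, all regenerated deterministically from code.

* ``fig2_space`` — the nine-state portion of the Tower of London problem
  space used throughout the worked examples, with goal ``s9`` and the
  five-problem running-example domain {s1, s3, s4, s7, s8};
* ``tol_full`` — the complete 36-state Tower of London move graph;
* ``table4_params`` — the elementary-transition β/η table of the worked
  MSP example (failure entries filled in as row residuals);
* ``ktol_structure`` — the eleven-state knowledge structure of the
  running example, written out explicitly so derivations can be checked
  against it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .knowledge import KnowledgeStructure, SkillMap
from .mspm import TransitionParams
from .spaces import GoalSpace, Problem, ProblemSpace, build_tol_space, make_sp_goal_space

__all__ = [
    "FIXTURES",
    "load_fixture",
    "fig2_space",
    "fig2_goal_space",
    "fig2_skill_map",
    "table4_params",
    "ktol_structure",
    "TOL_GOAL_STATE",
]

#: the designated goal state of the full-space study: arrangement 3 (the
#: (2,1,0) occupancy, whose states admit four legal moves), color coding 1
TOL_GOAL_STATE = "31"

_FIG2_EDGES = [
    ("s1", "a", "s2"),
    ("s1", "b", "s3"),
    ("s2", "b", "s4"),
    ("s3", "a", "s5"),
    ("s4", "A", "s6"),
    ("s5", "B", "s7"),
    ("s6", "B", "s8"),
    ("s7", "A", "s8"),
    ("s8", "A", "s9"),
]

_RUNNING_DOMAIN = ("s1", "s3", "s4", "s7", "s8")

# (i, j, beta_ij, eta_ij); failure entries are the row residuals
_TABLE4_ROWS = [
    ("s1", "s2", 0.36, 0.01),
    ("s1", "s3", 0.62, 0.03),
    ("s2", "s4", 0.99, 0.06),
    ("s3", "s5", 0.99, 0.08),
    ("s4", "s6", 0.99, 0.01),
    ("s5", "s7", 0.99, 0.09),
    ("s6", "s8", 0.99, 0.09),
    ("s7", "s8", 0.99, 0.09),
    ("s8", "s9", 0.99, 0.08),
]

_KTOL_STATES = [
    (),
    ("s8",),
    ("s4", "s8"),
    ("s7", "s8"),
    ("s4", "s7", "s8"),
    ("s1", "s4", "s8"),
    ("s3", "s7", "s8"),
    ("s1", "s4", "s7", "s8"),
    ("s3", "s4", "s7", "s8"),
    ("s1", "s3", "s7", "s8"),
    ("s1", "s3", "s4", "s7", "s8"),
]


def fig2_space() -> ProblemSpace:
    """The nine-state example portion of the ToL problem space."""
    return ProblemSpace.from_edges(_FIG2_EDGES)


def fig2_goal_space(restrict: bool = True) -> GoalSpace:
    """Shortest-path goal space on the nine-state example, goal ``s9``.

    With ``restrict`` (the default) the domain is cut down to the five
    problems of the running example.
    """
    gs = make_sp_goal_space(fig2_space(), "s9")
    if restrict:
        gs = gs.restrict_domain(_RUNNING_DOMAIN)
    return gs


def fig2_skill_map(match: str = "state") -> SkillMap:
    return SkillMap.from_goal_space(fig2_goal_space(), match=match)


def table4_params() -> TransitionParams:
    return TransitionParams.from_edge_table(fig2_goal_space(), _TABLE4_ROWS)


def ktol_structure() -> KnowledgeStructure:
    """The eleven-state knowledge structure of the running example."""
    domain = [Problem(s, "s9") for s in _RUNNING_DOMAIN]
    states = [
        frozenset(Problem(s, "s9") for s in st) for st in _KTOL_STATES
    ]
    return KnowledgeStructure.from_sets(domain, states)


@dataclass(frozen=True)
class Fixture:
    name: str
    obj: object


_LOADERS = {
    "fig2_space": fig2_space,
    "tol_full": build_tol_space,
    "table4_params": table4_params,
    "ktol_structure": ktol_structure,
}


def load_fixture(name: str):
    """Return the named fixture object; unknown names list the options."""
    try:
        return _LOADERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_LOADERS)}"
        ) from None


FIXTURES = tuple(sorted(_LOADERS))


def tol_goal_space(drop_one_move: bool = True) -> GoalSpace:
    """The full-space shortest-path goal space on the designated goal."""
    return make_sp_goal_space(build_tol_space(), TOL_GOAL_STATE, drop_one_move=drop_one_move)
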