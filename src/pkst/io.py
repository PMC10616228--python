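"""Serialization for spaces, structures, parameters, processes and studies.

Formats are plain text throughout:

* problem/goal spaces — JSON (states, operations, labeled edges, optional
  goal/failure/domain markers);
* knowledge structures — JSON (ordered domain + bit-strings) or CSV
  membership matrices (rows = states, columns = problems, entries 0/1);
* transition parameters — CSV with columns ``i, j, beta, eta``;
* solution-process logs — JSON lines, one record per administered
  problem;
* study configurations — YAML.

Probabilities are written as decimal text with 17 significant digits so
that every round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
import yaml

from .evaluation import StudyCondition
from .knowledge import KnowledgeStructure
from .mspm import SolutionProcess, TransitionParams
from .spaces import GoalSpace, Problem, ProblemSpace

__all__ = [
    "SchemaError",
    "space_to_dict",
    "space_from_dict",
    "write_space",
    "read_space",
    "goal_space_to_dict",
    "goal_space_from_dict",
    "write_goal_space",
    "read_goal_space",
    "structure_to_dict",
    "structure_from_dict",
    "write_structure",
    "read_structure",
    "write_structure_csv",
    "read_structure_csv",
    "write_params_csv",
    "read_params_csv",
    "write_process_log",
    "read_process_log",
    "read_study_config",
    "write_study_config",
]

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Raised when a serialized object violates its schema."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# -- spaces ----------------------------------------------------------------

def space_to_dict(space: ProblemSpace) -> dict:
    return {
        "states": sorted(space.states),
        "operations": sorted(space.operations),
        "edges": sorted([s, w, t] for s, w, t in space.edges()),
    }


def space_from_dict(data: dict) -> ProblemSpace:
    for key in ("states", "operations", "edges"):
        if key not in data:
            raise SchemaError(f"space object missing field {key!r}")
    space = ProblemSpace.from_edges(tuple(e) for e in data["edges"])
    declared = set(data["states"])
    if not space.states <= declared:
        raise SchemaError("edges reference undeclared states")
    if space.states != declared:
        # isolated states are allowed; re-add them
        space = ProblemSpace(
            frozenset(declared), frozenset(data["operations"]), dict(space.transitions)
        )
    return space


def goal_space_to_dict(gs: GoalSpace) -> dict:
    out = space_to_dict(gs.space)
    out["goal"] = gs.goal
    out["failure"] = gs.failure
    out["domain"] = [q.initial for q in gs.domain]
    out["distance"] = {s: int(d) for s, d in sorted(gs.distance.items())}
    return out


def goal_space_from_dict(data: dict) -> GoalSpace:
    for key in ("goal", "failure", "domain", "distance"):
        if key not in data:
            raise SchemaError(f"goal-space object missing field {key!r}")
    space = space_from_dict(data)
    goal, failure = data["goal"], data["failure"]
    domain = tuple(Problem(s, goal) for s in data["domain"])
    distance = {s: int(d) for s, d in data["distance"].items()}
    for w in space.operations:
        for s in (goal, failure):
            if space.apply(s, (w,)) != s:
                raise SchemaError(f"state {s!r} is not absorbing under {w!r}")
    return GoalSpace(space, goal, failure, domain, distance)


def write_space(space: ProblemSpace, path: str | Path) -> None:
    Path(path).write_text(json.dumps(space_to_dict(space), indent=1) + "\n")


def read_space(path: str | Path) -> ProblemSpace:
    return space_from_dict(json.loads(Path(path).read_text()))


def write_goal_space(gs: GoalSpace, path: str | Path) -> None:
    Path(path).write_text(json.dumps(goal_space_to_dict(gs), indent=1) + "\n")


def read_goal_space(path: str | Path) -> GoalSpace:
    return goal_space_from_dict(json.loads(Path(path).read_text()))


# -- knowledge structures --------------------------------------------------

def structure_to_dict(ks: KnowledgeStructure) -> dict:
    n = len(ks.domain)
    return {
        "domain": [q.initial for q in ks.domain],
        "goal": ks.domain[0].goal if ks.domain else None,
        "space": bool(ks.space_flag),
        "states": [
            "".join("1" if int(m) >> i & 1 else "0" for i in range(n))
            for m in ks.masks
        ],
    }


def structure_from_dict(data: dict) -> KnowledgeStructure:
    for key in ("domain", "goal", "states"):
        if key not in data:
            raise SchemaError(f"structure object missing field {key!r}")
    domain = [Problem(s, data["goal"]) for s in data["domain"]]
    n = len(domain)
    masks = []
    for k, bits in enumerate(data["states"]):
        if len(bits) != n or set(bits) - {"0", "1"}:
            raise SchemaError(f"state {k} is not a {n}-character bit-string")
        masks.append(sum(1 << i for i, b in enumerate(bits) if b == "1"))
    arr = np.array(sorted(set(masks)), dtype=np.int64)
    return KnowledgeStructure(tuple(sorted(domain)), arr, data.get("space", True))


def write_structure(ks: KnowledgeStructure, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_to_dict(ks), indent=1) + "\n")


def read_structure(path: str | Path) -> KnowledgeStructure:
    return structure_from_dict(json.loads(Path(path).read_text()))


def write_structure_csv(ks: KnowledgeStructure, path: str | Path) -> None:
    cols = [q.initial for q in ks.domain]
    rows = [
        {c: int(m) >> i & 1 for i, c in enumerate(cols)} for m in ks.masks
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_structure_csv(path: str | Path, goal: str) -> KnowledgeStructure:
    df = pd.read_csv(path)
    domain = [Problem(c, goal) for c in df.columns]
    if not df.isin([0, 1]).all().all():
        raise SchemaError("membership matrix entries must be 0/1")
    states = [
        frozenset(q for q, v in zip(domain, row) if v) for row in df.to_numpy()
    ]
    return KnowledgeStructure.from_sets(domain, states)


# -- transition parameters -------------------------------------------------

def write_params_csv(params: TransitionParams, path: str | Path) -> None:
    rows = [
        {"i": i, "j": j, "beta": _fmt(params.beta[(i, j)]), "eta": _fmt(params.eta[(i, j)])}
        for (i, j) in sorted(params.beta)
    ]
    pd.DataFrame(rows, columns=["i", "j", "beta", "eta"]).to_csv(path, index=False)


def read_params_csv(path: str | Path, goal: str, failure: str) -> TransitionParams:
    df = pd.read_csv(path, dtype={"i": str, "j": str}, float_precision="round_trip")
    for col in ("i", "j", "beta", "eta"):
        if col not in df.columns:
            raise SchemaError(f"parameter table missing column {col!r}")
    beta, eta = {}, {}
    for k, row in df.iterrows():
        b, e = float(row["beta"]), float(row["eta"])
        if not (0 <= b <= 1 and 0 <= e <= 1):
            raise SchemaError(f"row {k}: probability outside [0, 1]")
        beta[(row["i"], row["j"])] = b
        eta[(row["i"], row["j"])] = e
    return TransitionParams(goal, failure, beta, eta)


# -- process logs ----------------------------------------------------------

def write_process_log(
    processes: Iterable[tuple[int, SolutionProcess]],
    path: str | Path,
    failure: str = "f",
) -> None:
    """One JSON record per line: {subject, problem, visited, terminal}."""
    with open(path, "w") as fh:
        for subject, sp in processes:
            terminal = (
                "goal"
                if sp.terminal == sp.problem.goal
                else "failure" if sp.terminal == failure else "open"
            )
            fh.write(
                json.dumps(
                    {
                        "subject": subject,
                        "problem": sp.problem.initial,
                        "visited": list(sp.visited),
                        "terminal": terminal,
                    }
                )
                + "\n"
            )


def read_process_log(
    path: str | Path, gs: GoalSpace
) -> list[tuple[int, SolutionProcess]]:
    """Read and validate a process log against a goal space's move graph."""
    pairs = gs.elementary_pairs()
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"line {ln}: invalid JSON ({exc})") from None
            for key in ("subject", "problem", "visited"):
                if key not in rec:
                    raise SchemaError(f"line {ln}: missing field {key!r}")
            visited = tuple(rec["visited"])
            for i, j in zip(visited, visited[1:]):
                if (i, j) not in pairs:
                    raise SchemaError(
                        f"line {ln}: ({i!r}, {j!r}) is not an elementary transition"
                    )
            out.append(
                (int(rec["subject"]), SolutionProcess(Problem(rec["problem"], gs.goal), visited))
            )
    return out


# -- study configuration ---------------------------------------------------

def read_study_config(path: str | Path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "conditions" not in data:
        raise SchemaError("study config must be a mapping with a 'conditions' list")
    conditions = []
    for k, c in enumerate(data["conditions"]):
        try:
            conditions.append(
                StudyCondition(
                    model=c["model"],
                    structure=c["structure"],
                    error=float(c["error"]),
                    n_subjects=int(c["n"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"condition {k}: {exc}") from None
    return {
        "conditions": conditions,
        "engines": data.get("engines", ["cmp", "msp1", "msp2", "msp3"]),
        "seed": int(data.get("seed", 0)),
        "threshold": float(data.get("threshold", 0.5)),
    }


def write_study_config(
    conditions: Sequence[StudyCondition],
    path: str | Path,
    engines: Sequence[str] = ("cmp", "msp1", "msp2", "msp3"),
    seed: int = 0,
    threshold: float = 0.5,
) -> None:
    data = {
        "seed": seed,
        "threshold": threshold,
        "engines": list(engines),
        "conditions": [
            {
                "model": c.model,
                "structure": c.structure,
                "error": c.error,
                "n": c.n_subjects,
            }
            for c in conditions
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
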