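"""Competence and knowledge structures derived from a goal space.

A *skill map* ``(Q, Π, τ)`` assigns to each problem the set of solution
paths that solve it.  A *competence state* is a set of solution paths that
respects path inclusion (downward closed under the subpath relation ⊑),
and the *problem function* ``p(C) = {q : τ(q) ∩ C ≠ ∅}`` maps it to the
knowledge state it delineates.  The family ``{p(C)}`` over all competence
states is the derived *knowledge space*: a union-closed family containing
the empty set and the full domain.

The knowledge space is computed without enumerating the (potentially
astronomically large) competence space: the image of the down-set of a
single path, ``p(↓π)``, is an atom, and because down-sets generate all
competence states under union while ``p`` distributes over union, the
space is the union closure of the atoms together with ∅.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .spaces import GoalSpace, Problem, SolutionPath, enumerate_solution_paths, is_subpath

__all__ = [
    "SkillMap",
    "KnowledgeStructure",
    "problem_function",
    "derive_competence_space",
    "derive_knowledge_space",
    "states_containing",
]

#: explicit competence-space enumeration is refused beyond this many
#: candidate subsets; the knowledge space is still available via atoms
MAX_COMPETENCE_CANDIDATES = 2**20


@dataclass(frozen=True)
class SkillMap:
    """The triple (Q, Π, τ) plus the precomputed subpath order on Π."""

    domain: tuple[Problem, ...]
    paths: tuple[SolutionPath, ...]
    tau: Mapping[Problem, frozenset[SolutionPath]] = field(hash=False)
    #: ``below[π]`` = set of paths ρ with ρ ⊑ π (including π itself)
    below: Mapping[SolutionPath, frozenset[SolutionPath]] = field(hash=False)

    @classmethod
    def from_goal_space(cls, gs: GoalSpace, match: str = "state") -> "SkillMap":
        """Build the skill map of a goal space.

        ``match`` selects the subpath comparability: ``"state"`` is the
        formal definition (substring occurrence anchored at the matching
        trajectory state); ``"string"`` compares operation strings only.
        """
        tau = enumerate_solution_paths(gs)
        paths = tuple(sorted(set(itertools.chain.from_iterable(tau.values()))))
        below = {
            q: frozenset(p for p in paths if is_subpath(p, q, gs.space, match=match))
            for q in paths
        }
        return cls(tuple(gs.domain), paths, tau, below)

    def problem_of(self, path: SolutionPath) -> Problem:
        for q, ps in self.tau.items():
            if path in ps:
                return q
        raise KeyError(path.label)

    def respects_path_inclusion(self, C: Iterable[SolutionPath]) -> bool:
        cset = set(C)
        return all(self.below[p] <= cset for p in cset)


def problem_function(C: Iterable[SolutionPath], sm: SkillMap) -> frozenset[Problem]:
    """p(C) = {q ∈ Q : τ(q) ∩ C ≠ ∅}, the knowledge state delineated by C."""
    cset = frozenset(C)
    return frozenset(q for q in sm.domain if sm.tau[q] & cset)


def derive_competence_space(sm: SkillMap) -> list[frozenset[SolutionPath]]:
    """All competence states: the downward-closed subsets of (Π, ⊑).

    Explicit enumeration over all ``2^|Π|`` candidate subsets, guarded by
    :data:`MAX_COMPETENCE_CANDIDATES`; larger path sets should derive the
    knowledge space directly from atoms instead.
    """
    n = len(sm.paths)
    if 2**n > MAX_COMPETENCE_CANDIDATES:
        raise ValueError(
            f"competence space would scan 2^{n} subsets; "
            "derive the knowledge space from atoms instead"
        )
    below_masks = []
    index = {p: i for i, p in enumerate(sm.paths)}
    for p in sm.paths:
        m = 0
        for r in sm.below[p]:
            m |= 1 << index[r]
        below_masks.append(m)
    out = []
    for mask in range(2**n):
        if all(below_masks[i] & mask == below_masks[i] for i in range(n) if mask >> i & 1):
            out.append(frozenset(p for i, p in enumerate(sm.paths) if mask >> i & 1))
    return out


@dataclass(frozen=True)
class KnowledgeStructure:
    """A family of problem subsets over an ordered domain, as bit-masks.

    ``domain`` is ordered lexicographically by initial-state identifier;
    bit ``i`` of a mask marks membership of ``domain[i]``.  ``masks`` is a
    sorted, duplicate-free int64 array so that membership queries and
    likelihood arithmetic vectorize over the whole family.
    """

    domain: tuple[Problem, ...]
    masks: np.ndarray = field(hash=False)
    space_flag: bool = True

    def __post_init__(self) -> None:
        if len(self.domain) > 62:
            raise ValueError("bit-mask representation supports at most 62 problems")

    @classmethod
    def from_sets(
        cls,
        domain: Sequence[Problem],
        states: Iterable[Iterable[Problem]],
        space_flag: bool = True,
    ) -> "KnowledgeStructure":
        dom = tuple(sorted(domain))
        index = {q: i for i, q in enumerate(dom)}
        masks = set()
        for st in states:
            m = 0
            for q in st:
                m |= 1 << index[q]
            masks.add(m)
        arr = np.array(sorted(masks), dtype=np.int64)
        return cls(dom, arr, space_flag)

    def __len__(self) -> int:
        return len(self.masks)

    def __contains__(self, state: Iterable[Problem]) -> bool:
        index = {q: i for i, q in enumerate(self.domain)}
        m = 0
        for q in state:
            m |= 1 << index[q]
        i = int(np.searchsorted(self.masks, m))
        return i < len(self.masks) and self.masks[i] == m

    def state_sets(self) -> Iterator[frozenset[Problem]]:
        for m in self.masks:
            yield self.state_set(int(m))

    def state_set(self, mask: int) -> frozenset[Problem]:
        return frozenset(q for i, q in enumerate(self.domain) if mask >> i & 1)

    def membership(self, q: Problem) -> np.ndarray:
        """Boolean vector: which states contain problem ``q``."""
        try:
            bit = self.domain.index(q)
        except ValueError:
            raise KeyError(f"{q} is not a domain problem") from None
        return (self.masks >> bit & 1).astype(bool)

    def is_union_closed(self, rng: np.random.Generator | None = None, pairs: int | None = None) -> bool:
        """Check union closure, exhaustively or on random pairs."""
        sorted_masks = self.masks
        if pairs is None:
            it = itertools.combinations(sorted_masks.tolist(), 2)
        else:
            rng = rng or np.random.default_rng()
            idx = rng.integers(0, len(sorted_masks), size=(pairs, 2))
            it = ((int(sorted_masks[i]), int(sorted_masks[j])) for i, j in idx)
        mset = set(sorted_masks.tolist())
        return all(a | b in mset for a, b in it)


def _atom_masks(sm: SkillMap) -> list[int]:
    index = {q: i for i, q in enumerate(sorted(sm.domain))}
    atoms = set()
    for pi in sm.paths:
        m = 0
        for rho in sm.below[pi]:
            for q in sm.domain:
                if rho in sm.tau[q]:
                    m |= 1 << index[q]
        atoms.add(m)
    return sorted(atoms)


def derive_knowledge_space(sm: SkillMap) -> KnowledgeStructure:
    """The knowledge space {p(C) : C competence state}, via atom closure.

    Atoms are the images ``p(↓π)`` of single-path down-sets; the space is
    their union closure together with ∅.  The closure is a single pass:
    after folding in atom ``a``, the family holds every union of a subset
    of the atoms processed so far.
    """
    closure: set[int] = {0}
    for a in _atom_masks(sm):
        closure |= {m | a for m in closure}
    dom = tuple(sorted(sm.domain))
    arr = np.array(sorted(closure), dtype=np.int64)
    return KnowledgeStructure(dom, arr, space_flag=True)


def states_containing(ks: KnowledgeStructure, q: Problem) -> KnowledgeStructure:
    """The sub-family K_q of states containing problem q."""
    sel = ks.membership(q)
    return KnowledgeStructure(ks.domain, ks.masks[sel], space_flag=False)
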