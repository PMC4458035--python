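"""Selfing-pedigree data model, validation and traversal.

A divergent selection experiment (DSE) propagates inbred maize lineages by
single-seed-descent with truncation selection: each *progenitor* is one
selected plant together with the selfed seed lot it produced.  Because every
progenitor has exactly one parent, a pedigree is a forest whose roots are the
founder plants drawn from the initial seed lot (generation G0).

The module also defines the tabular schemas shared by the whole package:
``pedigree.csv``, ``phenotypes.csv`` and ``bands.csv`` (see :mod:`dsekit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

POPULATIONS = ("Early", "Late", "Control")
BACKGROUNDS = ("F252", "MBS")
DIGESTION_SYSTEMS = ("EcoRI_MseI", "EcoRI_MspI", "EcoRI_HpaII")


@dataclass(frozen=True)
class Progenitor:
    """One pedigree node: a selected plant and its selfed seed lot.

    ``parent_id`` is ``None`` exactly for founders (generation 0); a child's
    generation must be its parent's generation plus one.
    """

    id: str
    parent_id: Optional[str]
    generation: int
    family: str
    population: str
    background: str


@dataclass
class Violation:
    """A single pedigree-invariant violation (or warning)."""

    progenitor_id: str
    rule: str
    message: str
    warning: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        level = "warning" if self.warning else "error"
        return f"[{level}] {self.progenitor_id}: {self.rule} - {self.message}"


class Pedigree:
    """A forest of selfing lineages indexed by progenitor id."""

    def __init__(self, progenitors: Iterable[Progenitor]):
        self._by_id: dict[str, Progenitor] = {}
        for p in progenitors:
            if p.id in self._by_id:
                raise ValueError(f"duplicate progenitor id {p.id!r}")
            self._by_id[p.id] = p
        self._children: dict[str, list[str]] = {pid: [] for pid in self._by_id}
        for p in self._by_id.values():
            if p.parent_id is not None and p.parent_id in self._by_id:
                self._children[p.parent_id].append(p.id)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Progenitor]:
        return iter(self._by_id.values())

    def __contains__(self, pid: str) -> bool:
        return pid in self._by_id

    def __getitem__(self, pid: str) -> Progenitor:
        try:
            return self._by_id[pid]
        except KeyError:
            raise KeyError(f"no such progenitor: {pid!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def founders(self) -> list[Progenitor]:
        return [p for p in self if p.parent_id is None]

    def children(self, pid: str) -> list[Progenitor]:
        self[pid]
        return [self._by_id[c] for c in self._children[pid]]

    def generations(self) -> list[int]:
        return sorted({p.generation for p in self})

    def topological_order(self) -> list[Progenitor]:
        """Progenitors sorted by (generation, id): parents before children."""
        return sorted(self, key=lambda p: (p.generation, p.id))

    def trees(self) -> list[list[Progenitor]]:
        """Connected components, each rooted at a founder, in topological order."""
        out = []
        for root in sorted(self.founders(), key=lambda p: p.id):
            stack, comp = [root.id], []
            while stack:
                pid = stack.pop()
                comp.append(self._by_id[pid])
                stack.extend(sorted(self._children[pid], reverse=True))
            out.append(comp)
        return out

    def lineage(self, pid: str) -> list[Progenitor]:
        """Ancestors of ``pid`` ordered founder first, ``pid`` last."""
        node = self[pid]
        path = [node]
        seen = {node.id}
        while node.parent_id is not None:
            node = self[node.parent_id]
            if node.id in seen:
                raise ValueError(f"pedigree cycle through {node.id!r}")
            seen.add(node.id)
            path.append(node)
        path.reverse()
        return path


def validate_pedigree(pedigree: Pedigree) -> list[Violation]:
    """Check the structural invariants of a selfing pedigree.

    Returns an empty list iff the pedigree is valid.  Each violation names
    the offending progenitor and the rule broken.  A family descending from
    more than one founder is reported as a *warning* rather than an error:
    in the real experiment the two Late F252 subfamilies split from one
    lineage mid-experiment and share a family label history.
    """
    violations: list[Violation] = []
    for p in pedigree:
        if p.parent_id is None and p.generation != 0:
            violations.append(Violation(p.id, "founder-generation",
                                        "founder must be at generation 0"))
        if p.parent_id is not None:
            if p.generation == 0:
                violations.append(Violation(p.id, "nonfounder-generation",
                                            "generation 0 requires a null parent"))
            if p.parent_id not in pedigree:
                violations.append(Violation(p.id, "unresolved-parent",
                                            f"parent {p.parent_id!r} not in pedigree"))
            else:
                parent = pedigree[p.parent_id]
                if parent.generation != p.generation - 1:
                    violations.append(Violation(
                        p.id, "generation-gap",
                        f"parent at generation {parent.generation}, "
                        f"child at {p.generation}"))
        if p.population not in POPULATIONS:
            violations.append(Violation(p.id, "unknown-population",
                                        f"population {p.population!r}"))
        if p.generation < 0:
            violations.append(Violation(p.id, "negative-generation",
                                        f"generation {p.generation}"))

    # Family cohesion: every family should trace back to a single founder.
    family_founders: dict[str, set[str]] = {}
    for p in pedigree:
        try:
            root = pedigree.lineage(p.id)[0].id
        except (KeyError, ValueError):
            continue  # already reported above
        family_founders.setdefault(p.family, set()).add(root)
    for fam, roots in family_founders.items():
        if len(roots) > 1:
            members = sorted(pid for pid in pedigree.ids
                             if pedigree[pid].family == fam)
            violations.append(Violation(
                members[0], "family-multiple-founders",
                f"family {fam!r} descends from founders {sorted(roots)}",
                warning=True))
    return violations


def lineage(pedigree: Pedigree, pid: str) -> list[Progenitor]:
    """Functional alias for :meth:`Pedigree.lineage`."""
    return pedigree.lineage(pid)
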