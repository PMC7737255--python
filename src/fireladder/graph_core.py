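"""Per-terminology IS-A graph construction and cycle removal.

Each source vocabulary gets its own adjacency structure mapping every
concept to the set of its parents and the set of its children.  A PAR /
inverse_isa relationship row (cui1, cui2) contributes the edge
parent=cui2, child=cui1.  Self-loops are dropped at build time; directed
cycles are broken by a deterministic depth-limited DFS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .rrf_io import AtomRecord, RelRecord, SourceConfig

logger = logging.getLogger(__name__)


@dataclass
class RemovedEdge:
    sab: str
    child: str
    parent: str
    reason: str  # "self_loop" | "cycle_back_edge"


@dataclass
class TerminologyGraph:
    """Parent/child adjacency of one source vocabulary's IS-A hierarchy."""

    sab: str
    parents: dict[str, set[str]] = field(default_factory=dict)
    children: dict[str, set[str]] = field(default_factory=dict)

    def add_edge(self, child: str, parent: str) -> None:
        self.parents.setdefault(child, set()).add(parent)
        self.children.setdefault(parent, set()).add(child)
        self.parents.setdefault(parent, set())
        self.children.setdefault(child, set())

    def remove_edge(self, child: str, parent: str) -> None:
        self.parents[child].discard(parent)
        self.children[parent].discard(child)

    def has_edge(self, child: str, parent: str) -> bool:
        return parent in self.parents.get(child, ())

    @property
    def nodes(self) -> set[str]:
        return set(self.parents) | set(self.children)

    def n_edges(self) -> int:
        return sum(len(v) for v in self.parents.values())

    def copy(self) -> "TerminologyGraph":
        return TerminologyGraph(
            sab=self.sab,
            parents={k: set(v) for k, v in self.parents.items()},
            children={k: set(v) for k, v in self.children.items()},
        )

    def check_symmetry(self) -> bool:
        """x in children[p] iff p in parents[x]."""
        for child, ps in self.parents.items():
            for p in ps:
                if child not in self.children.get(p, ()):
                    return False
        for parent, cs in self.children.items():
            for c in cs:
                if parent not in self.parents.get(c, ()):
                    return False
        return True


@dataclass
class OntDagCollection:
    """All per-SAB graphs plus the atom-presence sets used for the
    "does not exist anywhere in terminology T" tests."""

    graphs: dict[str, TerminologyGraph]
    presence: dict[str, set[str]]
    removed_edges: list[RemovedEdge] = field(default_factory=list)
    dangling_edge_count: int = 0


def remove_cycles(
    graph: TerminologyGraph, max_depth: int
) -> tuple[TerminologyGraph, list[RemovedEdge]]:
    """Break directed cycles by deleting back edges found during DFS.

    A depth-first traversal is started from every node in ascending CUI
    order, following child edges and exploring at most ``max_depth`` edge
    levels.  Any edge that closes a path back onto the current DFS stack is
    deleted the moment it is seen and recorded as a ``cycle_back_edge``.
    Neighbor iteration is in ascending CUI order, so removal is
    deterministic.  Cycles longer than ``max_depth`` may survive.
    """
    g = graph.copy()
    removed: list[RemovedEdge] = []
    on_stack: set[str] = set()

    def visit(node: str, depth: int) -> None:
        if depth >= max_depth:
            return
        for child in sorted(g.children.get(node, ())):
            if not g.has_edge(child, node):
                continue  # removed earlier in this traversal
            if child in on_stack:
                g.remove_edge(child, node)
                removed.append(RemovedEdge(
                    sab=g.sab, child=child, parent=node,
                    reason="cycle_back_edge",
                ))
                continue
            on_stack.add(child)
            visit(child, depth + 1)
            on_stack.discard(child)

    for root in sorted(g.nodes):
        on_stack.add(root)
        visit(root, 0)
        on_stack.discard(root)
    return g, removed


def build_ontdag(
    atoms: Iterable[AtomRecord],
    rels: Iterable[RelRecord],
    config: SourceConfig,
) -> OntDagCollection:
    """Assemble the per-SAB graphs and presence sets.

    Duplicate relationship rows collapse to a single edge; self-loops are
    recorded and skipped; cycle removal runs per graph with the configured
    depth bound.  Edges whose endpoints lack atoms in their SAB are kept
    (nodes are defined by edge participation) but counted as dangling.
    """
    presence: dict[str, set[str]] = {sab: set() for sab in config.included_sabs}
    for atom in atoms:
        presence.setdefault(atom.sab, set()).add(atom.cui)

    graphs: dict[str, TerminologyGraph] = {
        sab: TerminologyGraph(sab=sab) for sab in config.included_sabs
    }
    removed: list[RemovedEdge] = []
    dangling = 0
    for rel in sorted(rels, key=lambda r: (r.sab, r.cui1, r.cui2)):
        g = graphs.setdefault(rel.sab, TerminologyGraph(sab=rel.sab))
        child, parent = rel.cui1, rel.cui2
        if child == parent:
            removed.append(RemovedEdge(
                sab=rel.sab, child=child, parent=parent, reason="self_loop",
            ))
            continue
        if g.has_edge(child, parent):
            continue
        pres = presence.get(rel.sab, set())
        if child not in pres or parent not in pres:
            dangling += 1
        g.add_edge(child, parent)

    for sab in sorted(graphs):
        graphs[sab], cyc_removed = remove_cycles(
            graphs[sab], config.max_cycle_depth
        )
        removed.extend(cyc_removed)

    if dangling:
        logger.warning(
            "%d IS-A edges reference a CUI with no retained atom in its SAB",
            dangling,
        )
    return OntDagCollection(
        graphs=graphs,
        presence=presence,
        removed_edges=removed,
        dangling_edge_count=dangling,
    )


REMOVED_EDGES_TSV_HEADER = "sab\tchild_cui\tparent_cui\treason"


def write_removed_edges(removed: Iterable[RemovedEdge], path: str | Path) -> None:
    """Diagnostic TSV of removed self-loops and cycle back edges."""
    rows = sorted(removed, key=lambda e: (e.sab, e.child, e.parent, e.reason))
    lines = [REMOVED_EDGES_TSV_HEADER]
    lines.extend(f"{e.sab}\t{e.child}\t{e.parent}\t{e.reason}" for e in rows)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
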