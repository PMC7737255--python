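"""Fire-ladder pattern detection across ordered terminology triples.

A fire ladder ties together a target terminology A, an upper source B and a
lower source C through three concepts a1, b2, c3 satisfying nine
constraints:

1. a1 is a node of A's hierarchy
2. a1 is a node of B's hierarchy
3. a1 has no atom in C
4. b2 is a child of a1 in B
5. b2 has no atom in A
6. b2 is a node of C's hierarchy
7. c3 is a child of b2 in C
8. c3 has no atom in B
9. c3 is a child of a1 in A

The "has no atom" tests use atom presence (any retained MRCONSO row for
that CUI/SAB), not graph-node membership: a concept can belong to a
terminology without participating in any IS-A link.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from .graph_core import OntDagCollection


@dataclass(frozen=True, order=True)
class FireLadderPattern:
    """One detected instance: the ordered (target, upper, lower) SABs and
    the three concept CUIs."""

    target_sab: str
    upper_sab: str
    lower_sab: str
    a1: str
    b2: str
    c3: str


def enumerate_triples(sabs: Sequence[str]) -> list[tuple[str, str, str]]:
    """All ordered 3-permutations of the given SABs, n!/(n-3)! of them,
    in lexicographic order of the input list."""
    sabs = list(sabs)
    if len(sabs) < 3:
        raise ValueError(f"need at least 3 SABs, got {len(sabs)}")
    if len(set(sabs)) != len(sabs):
        raise ValueError("duplicate SABs")
    return list(permutations(sabs, 3))


def _check_triple(dags: OntDagCollection, triple: tuple[str, str, str]) -> None:
    for sab in triple:
        if sab not in dags.graphs:
            raise ValueError(f"SAB {sab!r} not present in ontDAG collection")


def failed_constraints(
    dags: OntDagCollection,
    target: str,
    upper: str,
    lower: str,
    a1: str,
    b2: str,
    c3: str,
) -> frozenset[int]:
    """Indices (1-9) of the defining constraints that do NOT hold."""
    ga, gb, gc = dags.graphs[target], dags.graphs[upper], dags.graphs[lower]
    pres_a = dags.presence.get(target, set())
    pres_b = dags.presence.get(upper, set())
    pres_c = dags.presence.get(lower, set())
    failures = set()
    if a1 not in ga.nodes:
        failures.add(1)
    if a1 not in gb.nodes:
        failures.add(2)
    if a1 in pres_c:
        failures.add(3)
    if b2 not in gb.children.get(a1, ()):
        failures.add(4)
    if b2 in pres_a:
        failures.add(5)
    if b2 not in gc.nodes:
        failures.add(6)
    if c3 not in gc.children.get(b2, ()):
        failures.add(7)
    if c3 in pres_b:
        failures.add(8)
    if c3 not in ga.children.get(a1, ()):
        failures.add(9)
    return frozenset(failures)


def detect_fire_ladders(
    dags: OntDagCollection,
    triples: Iterable[tuple[str, str, str]],
) -> list[FireLadderPattern]:
    """Every (triple, a1, b2, c3) satisfying all nine constraints.

    Iterates a1 over nodes(A) ∩ nodes(B), then b2 over a1's children in B,
    then c3 over b2's children in C — the cheap join order.  The result is
    purely set-defined and returned in canonical sorted order.
    """
    out: list[FireLadderPattern] = []
    for triple in triples:
        _check_triple(dags, triple)
        target, upper, lower = triple
        ga, gb, gc = dags.graphs[target], dags.graphs[upper], dags.graphs[lower]
        pres_a = dags.presence.get(target, set())
        pres_b = dags.presence.get(upper, set())
        pres_c = dags.presence.get(lower, set())
        for a1 in ga.nodes & gb.nodes:
            if a1 in pres_c:
                continue
            children_a1_in_a = ga.children.get(a1, set())
            if not children_a1_in_a:
                continue
            for b2 in gb.children.get(a1, ()):
                if b2 in pres_a or b2 not in gc.nodes:
                    continue
                for c3 in gc.children.get(b2, ()):
                    if c3 in pres_b:
                        continue
                    if c3 in children_a1_in_a:
                        out.append(FireLadderPattern(
                            target_sab=target, upper_sab=upper,
                            lower_sab=lower, a1=a1, b2=b2, c3=c3,
                        ))
    out.sort()
    return out


def brute_force_ladders(
    dags: OntDagCollection,
    triples: Iterable[tuple[str, str, str]],
) -> list[FireLadderPattern]:
    """Testing oracle: enumerate every (a1, b2, c3) CUI combination from the
    three terminologies and check the nine constraints directly.

    Cubic in the CUI count — small inputs only.
    """
    out: list[FireLadderPattern] = []
    for triple in triples:
        _check_triple(dags, triple)
        target, upper, lower = triple
        universe = sorted(
            dags.graphs[target].nodes
            | dags.graphs[upper].nodes
            | dags.graphs[lower].nodes
            | dags.presence.get(target, set())
            | dags.presence.get(upper, set())
            | dags.presence.get(lower, set())
        )
        ga, gb, gc = dags.graphs[target], dags.graphs[upper], dags.graphs[lower]
        nodes_a, nodes_b, nodes_c = ga.nodes, gb.nodes, gc.nodes
        pres_a = dags.presence.get(target, set())
        pres_b = dags.presence.get(upper, set())
        pres_c = dags.presence.get(lower, set())
        # constraints grouped by the variable they mention; the conjunction
        # over all nine is unchanged, pruning just skips doomed inner loops
        for a1 in universe:
            if not (a1 in nodes_a and a1 in nodes_b and a1 not in pres_c):
                continue
            for b2 in universe:
                if not (
                    b2 in gb.children.get(a1, ())
                    and b2 not in pres_a
                    and b2 in nodes_c
                ):
                    continue
                for c3 in universe:
                    if (
                        c3 in gc.children.get(b2, ())
                        and c3 not in pres_b
                        and c3 in ga.children.get(a1, ())
                    ):
                        out.append(FireLadderPattern(
                            target_sab=target, upper_sab=upper,
                            lower_sab=lower, a1=a1, b2=b2, c3=c3,
                        ))
    out.sort()
    return out
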