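"""Candidate data sets and summaries derived from detected patterns.

Data Set 1 proposes importing B2 into the target terminology as a child of
A1 and parent of C3; patterns sharing (target, A1, B2, C3) across different
source permutations merge into one candidate.  Data Set 2 proposes
importing C3 into the upper source as a child of B2; in the default
"anchored" mode every qualifying sibling of a detected C3 under the same
B2 stem is admitted, in "strict" mode only the exact projection of the
pattern set is kept.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .graph_core import OntDagCollection
from .ladder_detect import FireLadderPattern
from .rrf_io import resolve_name

DATASET2_MODES = ("strict", "anchored")


@dataclass(frozen=True, order=True)
class ImportCandidate:
    """One Data Set 1 row: merged pattern group keyed by
    (target SAB, a1, b2, c3) with its contributing source permutations."""

    target_sab: str
    a1: str
    b2: str
    c3: str
    sources: tuple[tuple[str, str], ...]  # sorted (upper, lower) pairs


@dataclass(frozen=True, order=True)
class PairCandidate:
    """One Data Set 2 row: (B2, C3) pair from upper/lower sources."""

    upper_sab: str
    lower_sab: str
    b2: str
    c3: str
    anchor_a1: str | None = None


@dataclass(frozen=True, order=True)
class TripleSummary:
    """Pattern count for the unordered set of three terminologies."""

    sab_set: tuple[str, str, str]  # sorted
    pattern_count: int


def build_dataset1(
    patterns: Iterable[FireLadderPattern],
) -> list[ImportCandidate]:
    """Group patterns by (target, a1, b2, c3); one candidate per group."""
    groups: dict[tuple[str, str, str, str], set[tuple[str, str]]] = defaultdict(set)
    for p in patterns:
        groups[(p.target_sab, p.a1, p.b2, p.c3)].add((p.upper_sab, p.lower_sab))
    return sorted(
        ImportCandidate(
            target_sab=target, a1=a1, b2=b2, c3=c3,
            sources=tuple(sorted(sources)),
        )
        for (target, a1, b2, c3), sources in groups.items()
    )


def build_dataset2(
    dags: OntDagCollection,
    patterns: Iterable[FireLadderPattern],
    mode: str = "anchored",
) -> list[PairCandidate]:
    """Distinct (upper, lower, b2, c3) pairs for import of C3 into B.

    strict: the exact projection of the pattern set.
    anchored: for every stem (a1, b2, upper, lower) seen in some pattern,
    every child of b2 in the lower source that has no atom in the upper
    source qualifies — this admits sibling C3s under a detected stem.
    """
    if mode not in DATASET2_MODES:
        raise ValueError(f"unknown dataset2 mode {mode!r}")
    best_anchor: dict[tuple[str, str, str, str], str] = {}
    if mode == "strict":
        for p in patterns:
            key = (p.upper_sab, p.lower_sab, p.b2, p.c3)
            if key not in best_anchor or p.a1 < best_anchor[key]:
                best_anchor[key] = p.a1
        return sorted(
            PairCandidate(
                upper_sab=u, lower_sab=l, b2=b2, c3=c3, anchor_a1=a1
            )
            for (u, l, b2, c3), a1 in best_anchor.items()
        )
    stems = {(p.a1, p.b2, p.upper_sab, p.lower_sab) for p in patterns}
    for a1, b2, upper, lower in sorted(stems):
        pres_b = dags.presence.get(upper, set())
        gc = dags.graphs[lower]
        for c3 in sorted(gc.children.get(b2, ())):
            if c3 in pres_b:
                continue
            key = (upper, lower, b2, c3)
            if key not in best_anchor or a1 < best_anchor[key]:
                best_anchor[key] = a1
    return sorted(
        PairCandidate(upper_sab=u, lower_sab=l, b2=b2, c3=c3, anchor_a1=a1)
        for (u, l, b2, c3), a1 in best_anchor.items()
    )


def summarize_by_triple(
    patterns: Iterable[FireLadderPattern],
) -> list[TripleSummary]:
    """Pattern counts grouped by the unordered SAB set; counts conserve the
    total pattern count."""
    counts: dict[tuple[str, str, str], int] = defaultdict(int)
    for p in patterns:
        key = tuple(sorted((p.target_sab, p.upper_sab, p.lower_sab)))
        counts[key] += 1
    return sorted(
        TripleSummary(sab_set=key, pattern_count=n)
        for key, n in counts.items()
    )


DATASET1_TSV_HEADER = (
    "target_sab\ta1_cui\ta1_name\tb2_cui\tb2_name\tc3_cui\tc3_name\tsources"
)
DATASET2_TSV_HEADER = "upper_sab\tlower_sab\tb2_cui\tb2_name\tc3_cui\tc3_name"
SUMMARY_TSV_HEADER = "sab_set\tpattern_count"


def write_dataset1(
    cands: Iterable[ImportCandidate],
    path: str | Path,
    names: Mapping[tuple[str, str], str] | None = None,
) -> None:
    lines = [DATASET1_TSV_HEADER]
    for c in sorted(cands):
        upper_sabs = [u for u, _ in c.sources]
        lower_sabs = [l for _, l in c.sources]
        lines.append("\t".join((
            c.target_sab,
            c.a1, resolve_name(names, c.a1, c.target_sab, *upper_sabs),
            c.b2, resolve_name(names, c.b2, *upper_sabs),
            c.c3, resolve_name(names, c.c3, *lower_sabs, c.target_sab),
            ";".join(f"{u},{l}" for u, l in c.sources),
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_dataset2(
    cands: Iterable[PairCandidate],
    path: str | Path,
    names: Mapping[tuple[str, str], str] | None = None,
) -> None:
    lines = [DATASET2_TSV_HEADER]
    for c in sorted(cands):
        lines.append("\t".join((
            c.upper_sab, c.lower_sab,
            c.b2, resolve_name(names, c.b2, c.upper_sab, c.lower_sab),
            c.c3, resolve_name(names, c.c3, c.lower_sab),
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_summary(
    summaries: Iterable[TripleSummary], path: str | Path
) -> None:
    lines = [SUMMARY_TSV_HEADER]
    for s in sorted(summaries):
        lines.append(f"{','.join(s.sab_set)}\t{s.pattern_count}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
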