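"""Synthetic RRF fixtures with known ground truth.

Generates MRCONSO/MRREL files in the standard dialect containing planted
fire ladders, near-miss decoys (each breaking one of the nine defining
constraints), planted IS-A cycles, language/suppression chaff and inert
filler, plus a JSON ground-truth file.  Output is deterministic for a
given seed.

Synthetic CUIs live in a reserved high range (C9xxxxxx) so they cannot
collide with the real CUIs used by the worked HPO/NCIt/SNOMED CT example.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

from .ladder_detect import FireLadderPattern
from .rrf_io import (
    AtomRecord,
    RelRecord,
    format_mrconso_row,
    format_mrrel_row,
)

_CUI_BASE = 9000001


@dataclass
class FixtureSpec:
    sabs: list[str]
    n_concepts_per_sab: int
    n_planted_ladders: int = 0
    n_decoys: int = 0
    n_cycles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sabs) < 3 or len(set(self.sabs)) != len(self.sabs):
            raise ValueError("need at least 3 distinct SABs")
        if self.n_concepts_per_sab < 1:
            raise ValueError("n_concepts_per_sab must be positive")
        for name in ("n_planted_ladders", "n_decoys", "n_cycles"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    planted_patterns: list[FireLadderPattern] = field(default_factory=list)
    planted_cycle_edges: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_descriptions: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_patterns": [vars(p) for p in self.planted_patterns],
            "planted_cycle_edges": [list(e) for e in self.planted_cycle_edges],
            "decoy_descriptions": self.decoy_descriptions,
        }


class _Builder:
    def __init__(self, rng: random.Random):
        self.rng = rng
        self._next = _CUI_BASE
        self.atoms: set[AtomRecord] = set()
        self.rels: set[RelRecord] = set()
        self.used: dict[str, set[str]] = {}

    def new_cui(self) -> str:
        cui = f"C{self._next:07d}"
        self._next += 1
        if self._next > 9999999:
            raise ValueError("synthetic CUI range exhausted")
        return cui

    def atom(self, cui: str, sab: str, **kw) -> None:
        self.used.setdefault(sab, set()).add(cui)
        self.atoms.add(AtomRecord(
            cui=cui, sab=sab,
            code=kw.get("code", f"{sab}:{cui[1:]}"),
            lat=kw.get("lat", "ENG"),
            tty=kw.get("tty", "PT"),
            str_name=kw.get("str_name", f"Synthetic concept {cui} in {sab}"),
            suppress=kw.get("suppress", "N"),
        ))

    def edge(self, child: str, parent: str, sab: str, **kw) -> None:
        self.used.setdefault(sab, set()).add(child)
        self.used.setdefault(sab, set()).add(parent)
        self.rels.add(RelRecord(
            cui1=child, cui2=parent, sab=sab,
            rel=kw.get("rel", "PAR"), rela=kw.get("rela", "inverse_isa"),
            suppress=kw.get("suppress", "N"),
        ))


def _plant_ladder(b: _Builder, triple: tuple[str, str, str]) -> FireLadderPattern:
    target, upper, lower = triple
    a1, b2, c3 = b.new_cui(), b.new_cui(), b.new_cui()
    for cui, sab in ((a1, target), (a1, upper), (b2, upper), (b2, lower),
                     (c3, lower), (c3, target)):
        b.atom(cui, sab)
    b.edge(b2, a1, upper)   # constraint 4
    b.edge(c3, b2, lower)   # constraint 7
    b.edge(c3, a1, target)  # constraint 9
    return FireLadderPattern(
        target_sab=target, upper_sab=upper, lower_sab=lower,
        a1=a1, b2=b2, c3=c3,
    )


def _plant_decoy(
    b: _Builder, triple: tuple[str, str, str], constraint: int, decoy_id: str
) -> dict:
    """An almost-ladder that breaks the given constraint (1-9).

    Node-membership constraints 1, 2 and 6 can only be broken together
    with the edge constraint that entails them (9, 4 and 7 respectively);
    the remaining six break exactly the named constraint.
    """
    target, upper, lower = triple
    a1, b2, c3 = b.new_cui(), b.new_cui(), b.new_cui()
    for cui, sab in ((a1, target), (a1, upper), (b2, upper), (b2, lower),
                     (c3, lower), (c3, target)):
        b.atom(cui, sab)

    def dummy(sab: str) -> str:
        cui = b.new_cui()
        b.atom(cui, sab)
        return cui

    edges = {  # the intact ladder legs, dropped/replaced per constraint
        "upper": (b2, a1, upper),
        "lower": (c3, b2, lower),
        "target": (c3, a1, target),
    }
    if constraint == 1:       # a1 not a node of A: re-root c3 under a dummy
        edges["target"] = (c3, dummy(target), target)
    elif constraint == 2:     # a1 not a node of B
        edges["upper"] = (b2, dummy(upper), upper)
    elif constraint == 3:     # a1 exists in C
        b.atom(a1, lower)
    elif constraint == 4:     # b2 not a child of a1 in B, a1 still a B node
        edges["upper"] = (b2, dummy(upper), upper)
        b.edge(dummy(upper), a1, upper)
    elif constraint == 5:     # b2 exists in A
        b.atom(b2, target)
    elif constraint == 6:     # b2 not a node of C
        edges["lower"] = (c3, dummy(lower), lower)
    elif constraint == 7:     # c3 not a child of b2 in C, b2 still a C node
        edges["lower"] = (c3, dummy(lower), lower)
        b.edge(dummy(lower), b2, lower)
    elif constraint == 8:     # c3 exists in B
        b.atom(c3, upper)
    elif constraint == 9:     # c3 not a child of a1 in A, a1 still an A node
        edges["target"] = (c3, dummy(target), target)
        b.edge(dummy(target), a1, target)
    else:
        raise ValueError(f"constraint index {constraint} out of range 1-9")
    for child, parent, sab in edges.values():
        b.edge(child, parent, sab)
    return {
        "decoy_id": decoy_id,
        "violated_constraint": constraint,
        "target_sab": target, "upper_sab": upper, "lower_sab": lower,
        "a1": a1, "b2": b2, "c3": c3,
    }


def _plant_cycle(
    b: _Builder, sab: str, length: int = 3
) -> list[tuple[str, str, str]]:
    cuis = [b.new_cui() for _ in range(length)]
    for cui in cuis:
        b.atom(cui, sab)
    edges = []
    for i, parent in enumerate(cuis):
        child = cuis[(i + 1) % length]
        b.edge(child, parent, sab)
        edges.append((sab, child, parent))
    return edges


def _render(
    b: _Builder, out_dir: Path
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conso = out_dir / "MRCONSO.RRF"
    rel = out_dir / "MRREL.RRF"
    atom_rows = [format_mrconso_row(a) for a in sorted(b.atoms)]
    rel_rows = [format_mrrel_row(r) for r in sorted(b.rels)]
    conso.write_text("\n".join(atom_rows) + ("\n" if atom_rows else ""),
                     encoding="utf-8")
    rel.write_text("\n".join(rel_rows) + ("\n" if rel_rows else ""),
                   encoding="utf-8")
    return conso, rel


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    """Write MRCONSO.RRF / MRREL.RRF / ground_truth.json under ``out_dir``.

    Planted ladders are detectable, decoys are not; chaff includes a
    non-English atom and suppressed atom/relationship rows that the default
    filters drop.  Raises if the planted structures exceed the per-SAB
    concept budget.
    """
    rng = random.Random(spec.seed)
    b = _Builder(rng)
    gt = GroundTruth()
    triples = list(permutations(spec.sabs, 3))

    for _ in range(spec.n_planted_ladders):
        triple = triples[rng.randrange(len(triples))]
        gt.planted_patterns.append(_plant_ladder(b, triple))
    for i in range(spec.n_decoys):
        triple = triples[rng.randrange(len(triples))]
        constraint = (i % 9) + 1
        gt.decoy_descriptions.append(
            _plant_decoy(b, triple, constraint, decoy_id=f"decoy{i:03d}")
        )
    for _ in range(spec.n_cycles):
        sab = spec.sabs[rng.randrange(len(spec.sabs))]
        gt.planted_cycle_edges.extend(_plant_cycle(b, sab))

    over = {
        sab: len(cuis) for sab, cuis in b.used.items()
        if len(cuis) > spec.n_concepts_per_sab
    }
    if over:
        raise ValueError(
            f"planted structures exceed n_concepts_per_sab={spec.n_concepts_per_sab}: {over}"
        )

    # inert filler: single-SAB concepts, optionally wired into a small
    # forest; cannot participate in any cross-SAB pattern
    for sab in spec.sabs:
        fillers: list[str] = []
        while len(b.used.get(sab, set())) < spec.n_concepts_per_sab:
            cui = b.new_cui()
            b.atom(cui, sab)
            fillers.append(cui)
        for i in range(1, len(fillers)):
            if rng.random() < 0.5:
                b.edge(fillers[i], fillers[rng.randrange(i)], sab)

    # chaff: rows the configured filters must drop
    anchor = min(b.atoms)
    b.atom(anchor.cui, anchor.sab, code=anchor.code + ".FRE",
           lat="FRE", str_name="Concept synthetique " + anchor.cui)
    b.atom(anchor.cui, anchor.sab, code=anchor.code + ".SUP",
           suppress="O", str_name="Suppressed synonym " + anchor.cui)
    if b.rels:
        r = min(b.rels)
        b.edge(r.cui1, r.cui2, r.sab, suppress="O")        # suppressed dup
        b.edge(r.cui1, r.cui2, r.sab, rel="CHD", rela="")  # non IS-A label
        b.edge(r.cui1, r.cui2, r.sab, rel="PAR", rela="")  # PAR without rela

    conso, rel = _render(b, Path(out_dir))
    gt_path = Path(out_dir) / "ground_truth.json"
    gt_path.write_text(json.dumps(gt.to_dict(), indent=2) + "\n",
                       encoding="utf-8")
    return conso, rel, gt


# ---------------------------------------------------------------------------
# Worked example: intestinal atresia concepts across HPO, NCIt and SNOMED CT.
# B2 and the colonic-atresia confounder carry their real UMLS CUIs; the two
# concepts whose CUIs are not fixed by the source material use reserved
# synthetic CUIs.
# ---------------------------------------------------------------------------

FIG3_SABS = ("HPO", "NCI", "SNOMEDCT_US")
FIG3_A1 = "C9900001"   # Intestinal atresia (HPO + NCIt)
FIG3_B2 = "C0345203"   # Large intestine atresia (NCIt + SNOMED CT)
FIG3_C3 = "C9900002"   # Rectal atresia / Congenital atresia of rectum
FIG3_COLONIC = "C0266190"  # Colonic atresia (HPO only; distinct CUI)

FIG3_PATTERN = FireLadderPattern(
    target_sab="HPO", upper_sab="NCI", lower_sab="SNOMEDCT_US",
    a1=FIG3_A1, b2=FIG3_B2, c3=FIG3_C3,
)


def fig3_fixture(out_dir: str | Path) -> tuple[Path, Path, GroundTruth]:
    """The worked three-terminology example with its printed source codes."""
    rng = random.Random(0)
    b = _Builder(rng)
    b.atom(FIG3_A1, "HPO", code="HP:0011100", str_name="Intestinal atresia")
    b.atom(FIG3_A1, "NCI", code="C84790", str_name="Intestinal Atresia")
    b.atom(FIG3_B2, "NCI", code="C98827", str_name="Large Intestine Atresia")
    b.atom(FIG3_B2, "SNOMEDCT_US", code="204711007",
           str_name="Atresia of large intestine")
    b.atom(FIG3_C3, "HPO", code="HP:0025023", str_name="Rectal atresia")
    b.atom(FIG3_C3, "SNOMEDCT_US", code="91375006",
           str_name="Congenital atresia of rectum")
    b.atom(FIG3_COLONIC, "HPO", code="HP:0010448", str_name="Colonic atresia")
    # IS-A legs: child, parent, sab
    b.edge(FIG3_B2, FIG3_A1, "NCI")
    b.edge(FIG3_C3, FIG3_B2, "SNOMEDCT_US")
    b.edge(FIG3_C3, FIG3_A1, "HPO")
    b.edge(FIG3_COLONIC, FIG3_A1, "HPO")
    conso, rel = _render(b, Path(out_dir))
    gt = GroundTruth(planted_patterns=[FIG3_PATTERN])
    gt_path = Path(out_dir) / "ground_truth.json"
    gt_path.write_text(json.dumps(gt.to_dict(), indent=2) + "\n",
                       encoding="utf-8")
    return conso, rel, gt
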