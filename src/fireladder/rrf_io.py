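"""Reading and writing the UMLS RRF dialect (MRCONSO / MRREL) and detection outputs.

RRF files are UTF-8, pipe-delimited with a trailing pipe and no quoting or
escaping.  There is no header row; columns are addressed positionally using
the 2018AB release layout (see :data:`MRCONSO_COLUMNS` and
:data:`MRREL_COLUMNS`).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger(__name__)

CUI_PATTERN = re.compile(r"^C\d{7}$")

#: 2018AB MRCONSO column order (18 columns, trailing pipe).
MRCONSO_COLUMNS = (
    "CUI", "LAT", "TS", "LUI", "STT", "SUI", "ISPREF", "AUI", "SAUI",
    "SCUI", "SDUI", "SAB", "TTY", "CODE", "STR", "SRL", "SUPPRESS", "CVF",
)

#: 2018AB MRREL column order (16 columns, trailing pipe).
MRREL_COLUMNS = (
    "CUI1", "AUI1", "STYPE1", "REL", "CUI2", "AUI2", "STYPE2", "RELA",
    "RUI", "SRUI", "SAB", "SL", "RG", "DIR", "SUPPRESS", "CVF",
)

_CONSO_IDX = {name: i for i, name in enumerate(MRCONSO_COLUMNS)}
_REL_IDX = {name: i for i, name in enumerate(MRREL_COLUMNS)}


class RRFParseError(ValueError):
    """A malformed RRF row; carries the 1-based line number."""

    def __init__(self, path: Path | str, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True, order=True)
class AtomRecord:
    """One concept-name row from MRCONSO."""

    cui: str
    sab: str
    code: str
    lat: str = "ENG"
    tty: str = "PT"
    str_name: str = ""
    suppress: str = "N"

    def __post_init__(self) -> None:
        if not CUI_PATTERN.match(self.cui):
            raise ValueError(f"invalid CUI {self.cui!r}")
        if not self.sab:
            raise ValueError("empty SAB")
        if not self.str_name:
            raise ValueError("empty concept string")


@dataclass(frozen=True, order=True)
class RelRecord:
    """One relationship row from MRREL.

    ``rel``/``rela`` follow the UMLS reading: the row asserts that ``cui2``
    has relationship ``rel`` to ``cui1``, so a PAR row means cui2 is a
    parent of cui1.
    """

    cui1: str
    cui2: str
    sab: str
    rel: str = "PAR"
    rela: str = "inverse_isa"
    suppress: str = "N"

    def __post_init__(self) -> None:
        for cui in (self.cui1, self.cui2):
            if not CUI_PATTERN.match(cui):
                raise ValueError(f"invalid CUI {cui!r}")


@dataclass
class SourceConfig:
    """Which sources, language and filters to apply when reading RRF files."""

    included_sabs: Sequence[str]
    excluded_sabs: Sequence[str] = ()
    language: str = "ENG"
    drop_suppressed: bool = True
    max_cycle_depth: int = 5

    def __post_init__(self) -> None:
        inc = list(self.included_sabs)
        if not inc:
            raise ValueError("included_sabs must be non-empty")
        if len(set(inc)) != len(inc):
            raise ValueError("included_sabs contains duplicates")
        overlap = set(inc) & set(self.excluded_sabs)
        if overlap:
            raise ValueError(f"SABs both included and excluded: {sorted(overlap)}")
        if self.max_cycle_depth < 1:
            raise ValueError("max_cycle_depth must be positive")


#: The ten source vocabularies analysed by default, in UMLS release spelling.
DEFAULT_INCLUDED_SABS = (
    "SNOMEDCT_US", "NCI", "MEDCIN", "ATC", "CPM",
    "CPT", "FMA", "GO", "HPO", "UMD",
)
DEFAULT_EXCLUDED_SABS = ("SNOMEDCT_VET", "UWDA")


def default_config() -> SourceConfig:
    return SourceConfig(
        included_sabs=list(DEFAULT_INCLUDED_SABS),
        excluded_sabs=list(DEFAULT_EXCLUDED_SABS),
    )


def read_config(path: str | Path) -> "RunConfig":
    """Load a YAML key-value run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(
        source=SourceConfig(
            included_sabs=data.get("sabs", list(DEFAULT_INCLUDED_SABS)),
            excluded_sabs=data.get("excluded_sabs", list(DEFAULT_EXCLUDED_SABS)),
            language=data.get("language", "ENG"),
            drop_suppressed=bool(data.get("drop_suppressed", True)),
            max_cycle_depth=int(data.get("max_cycle_depth", 5)),
        ),
        dataset2_mode=data.get("dataset2_mode", "anchored"),
        seed=int(data.get("seed", 0)),
    )


@dataclass
class RunConfig:
    source: SourceConfig
    dataset2_mode: str = "anchored"
    seed: int = 0


def _split_row(line: str, ncols: int, path: Path | str, lineno: int) -> list[str]:
    # rows end with a trailing pipe, so splitting yields ncols + 1 fields
    fields = line.rstrip("\n").split("|")
    if len(fields) != ncols + 1 or fields[-1] != "":
        raise RRFParseError(
            path, lineno,
            f"expected {ncols} pipe-delimited columns with trailing pipe, "
            f"got {len(fields) - 1}",
        )
    return fields[:ncols]


def read_mrconso(path: str | Path, config: SourceConfig) -> list[AtomRecord]:
    """Parse MRCONSO.RRF, keeping rows that pass the configured filters.

    Rows are kept when SAB is included, LAT matches the configured language
    and (if ``drop_suppressed``) SUPPRESS is "N".  Output order is canonical:
    sorted by (cui, sab, code).
    """
    included = set(config.included_sabs)
    out: list[AtomRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_row(line, len(MRCONSO_COLUMNS), path, lineno)
            sab = f[_CONSO_IDX["SAB"]]
            if sab not in included:
                continue
            if f[_CONSO_IDX["LAT"]] != config.language:
                continue
            suppress = f[_CONSO_IDX["SUPPRESS"]]
            if config.drop_suppressed and suppress != "N":
                continue
            try:
                out.append(AtomRecord(
                    cui=f[_CONSO_IDX["CUI"]],
                    lat=f[_CONSO_IDX["LAT"]],
                    sab=sab,
                    tty=f[_CONSO_IDX["TTY"]],
                    code=f[_CONSO_IDX["CODE"]],
                    str_name=f[_CONSO_IDX["STR"]],
                    suppress=suppress,
                ))
            except ValueError as exc:
                raise RRFParseError(path, lineno, str(exc)) from exc
    if not out:
        logger.warning("no MRCONSO rows retained from %s after filtering", path)
    out.sort(key=lambda a: (a.cui, a.sab, a.code))
    return out


def read_mrrel(path: str | Path, config: SourceConfig) -> list[RelRecord]:
    """Parse MRREL.RRF keeping only IS-A rows (REL=PAR with RELA=inverse_isa)
    from included sources.  Canonical order: sorted by (cui1, cui2, sab)."""
    included = set(config.included_sabs)
    out: list[RelRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _split_row(line, len(MRREL_COLUMNS), path, lineno)
            if f[_REL_IDX["REL"]] != "PAR" or f[_REL_IDX["RELA"]] != "inverse_isa":
                continue
            sab = f[_REL_IDX["SAB"]]
            if sab not in included:
                continue
            suppress = f[_REL_IDX["SUPPRESS"]]
            if config.drop_suppressed and suppress not in ("N", ""):
                continue
            try:
                out.append(RelRecord(
                    cui1=f[_REL_IDX["CUI1"]],
                    rel=f[_REL_IDX["REL"]],
                    cui2=f[_REL_IDX["CUI2"]],
                    rela=f[_REL_IDX["RELA"]],
                    sab=sab,
                    suppress=suppress,
                ))
            except ValueError as exc:
                raise RRFParseError(path, lineno, str(exc)) from exc
    if not out:
        logger.warning("no MRREL rows retained from %s after filtering", path)
    out.sort(key=lambda r: (r.cui1, r.cui2, r.sab))
    return out


def format_mrconso_row(atom: AtomRecord) -> str:
    """Render an AtomRecord as a full 2018AB MRCONSO line (trailing pipe)."""
    f = [""] * len(MRCONSO_COLUMNS)
    f[_CONSO_IDX["CUI"]] = atom.cui
    f[_CONSO_IDX["LAT"]] = atom.lat
    f[_CONSO_IDX["TS"]] = "S"
    f[_CONSO_IDX["ISPREF"]] = "Y"
    f[_CONSO_IDX["SAB"]] = atom.sab
    f[_CONSO_IDX["TTY"]] = atom.tty
    f[_CONSO_IDX["CODE"]] = atom.code
    f[_CONSO_IDX["STR"]] = atom.str_name
    f[_CONSO_IDX["SRL"]] = "0"
    f[_CONSO_IDX["SUPPRESS"]] = atom.suppress
    return "|".join(f) + "|"


def format_mrrel_row(rel: RelRecord) -> str:
    """Render a RelRecord as a full 2018AB MRREL line (trailing pipe)."""
    f = [""] * len(MRREL_COLUMNS)
    f[_REL_IDX["CUI1"]] = rel.cui1
    f[_REL_IDX["STYPE1"]] = "CUI"
    f[_REL_IDX["REL"]] = rel.rel
    f[_REL_IDX["CUI2"]] = rel.cui2
    f[_REL_IDX["STYPE2"]] = "CUI"
    f[_REL_IDX["RELA"]] = rel.rela
    f[_REL_IDX["SAB"]] = rel.sab
    f[_REL_IDX["SL"]] = rel.sab
    f[_REL_IDX["SUPPRESS"]] = rel.suppress
    return "|".join(f) + "|"


def build_name_index(atoms: Iterable[AtomRecord]) -> dict[tuple[str, str], str]:
    """Display name per (CUI, SAB): the lexicographically first retained string."""
    names: dict[tuple[str, str], str] = {}
    for atom in atoms:
        key = (atom.cui, atom.sab)
        if key not in names or atom.str_name < names[key]:
            names[key] = atom.str_name
    return names


def resolve_name(
    names: Mapping[tuple[str, str], str] | None, cui: str, *sabs: str
) -> str:
    """Look up a display name for ``cui``, trying each SAB in order."""
    if not names:
        return ""
    for sab in sabs:
        name = names.get((cui, sab))
        if name:
            return name
    # fall back to any source that has the concept
    candidates = sorted(v for (c, _s), v in names.items() if c == cui)
    return candidates[0] if candidates else ""


PATTERN_TSV_HEADER = (
    "target_sab\tupper_sab\tlower_sab\t"
    "a1_cui\ta1_name\tb2_cui\tb2_name\tc3_cui\tc3_name"
)


def _pattern_sort_key(p):
    return (p.target_sab, p.upper_sab, p.lower_sab, p.a1, p.b2, p.c3)


def write_patterns(
    patterns,
    path: str | Path,
    format: str = "tsv",
    names: Mapping[tuple[str, str], str] | None = None,
) -> None:
    """Serialize detected patterns deterministically (canonical sort order).

    ``format`` is ``"tsv"`` (header + one row per pattern) or ``"json"``
    (array of objects).  Byte output depends only on the pattern set.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}")
    ordered = sorted(patterns, key=_pattern_sort_key)
    rows = []
    for p in ordered:
        rows.append({
            "target_sab": p.target_sab,
            "upper_sab": p.upper_sab,
            "lower_sab": p.lower_sab,
            "a1_cui": p.a1,
            "a1_name": resolve_name(names, p.a1, p.target_sab, p.upper_sab),
            "b2_cui": p.b2,
            "b2_name": resolve_name(names, p.b2, p.upper_sab, p.lower_sab),
            "c3_cui": p.c3,
            "c3_name": resolve_name(names, p.c3, p.lower_sab, p.target_sab),
        })
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(rows, indent=2) + "\n", encoding="utf-8")
        return
    lines = [PATTERN_TSV_HEADER]
    for r in rows:
        lines.append("\t".join(str(r[k]) for k in (
            "target_sab", "upper_sab", "lower_sab",
            "a1_cui", "a1_name", "b2_cui", "b2_name", "c3_cui", "c3_name",
        )))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
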