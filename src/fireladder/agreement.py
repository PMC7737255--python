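"""Two-rater agreement statistics on binary import / non-import decisions.

Cohen's kappa and Krippendorff's alpha are computed from a 2x2 contingency
of the raters' decisions.  Alpha uses the closed form for the two-rater,
complete-data, nominal (binary) special case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

IMPORT = "import"
NON_IMPORT = "non_import"
DECISIONS = (IMPORT, NON_IMPORT)


class UndefinedStatisticError(ZeroDivisionError):
    """The statistic is undefined for this contingency (no chance
    disagreement to correct for)."""


class InconsistentMarginalsError(ValueError):
    """Marginal totals do not describe any non-negative 2x2 table."""


@dataclass(frozen=True)
class RatingContingency:
    """Counts: a = both import, b = rater1 import only, c = rater2 import
    only, d = both non-import."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency has zero total count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_from_marginals(
    n: int, r1_import: int, r2_import: int, both_import: int
) -> RatingContingency:
    """Solve the unique 2x2 table with the given total, per-rater import
    counts and both-import count."""
    a = both_import
    b = r1_import - a
    c = r2_import - a
    d = n - a - b - c
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0:
            raise InconsistentMarginalsError(
                f"derived cell {name} = {v} is negative "
                f"(n={n}, r1_import={r1_import}, r2_import={r2_import}, "
                f"both_import={both_import})"
            )
    return RatingContingency(a=a, b=b, c=c, d=d)


def cohen_kappa(ct: RatingContingency) -> float:
    """kappa = (po - pe) / (1 - pe), with po the observed agreement rate and
    pe the product-of-marginals chance agreement."""
    n = ct.n
    po = (ct.a + ct.d) / n
    pe = ((ct.a + ct.b) * (ct.a + ct.c) + (ct.c + ct.d) * (ct.b + ct.d)) / n**2
    if pe == 1.0:
        raise UndefinedStatisticError("chance agreement pe = 1; kappa undefined")
    return (po - pe) / (1 - pe)


def krippendorff_alpha(ct: RatingContingency) -> float:
    """Nominal alpha for two raters, binary categories, no missing data.

    Do = (b + c)/n; De = 2 * n_imp * n_non / (N (N - 1)) with
    n_imp = 2a + b + c, n_non = 2d + b + c and N = 2n pairable values.
    """
    n = ct.n
    n_imp = 2 * ct.a + ct.b + ct.c
    n_non = 2 * ct.d + ct.b + ct.c
    big_n = 2 * n
    if big_n < 2 or n_imp == 0 or n_non == 0:
        raise UndefinedStatisticError(
            "expected disagreement De = 0; alpha undefined"
        )
    do = (ct.b + ct.c) / n
    de = 2 * n_imp * n_non / (big_n * (big_n - 1))
    return 1 - do / de


def tabulate(table: Iterable[tuple[str, str, str]]) -> RatingContingency:
    """Count the four decision combinations of a (unit, rater1, rater2)
    table.  Unit ids must be unique; decisions must be import/non_import."""
    seen: set[str] = set()
    a = b = c = d = 0
    n_rows = 0
    for unit, d1, d2 in table:
        n_rows += 1
        if unit in seen:
            raise ValueError(f"duplicate unit id {unit!r}")
        seen.add(unit)
        for dec in (d1, d2):
            if dec not in DECISIONS:
                raise ValueError(f"unit {unit!r}: unknown decision {dec!r}")
        if d1 == IMPORT and d2 == IMPORT:
            a += 1
        elif d1 == IMPORT:
            b += 1
        elif d2 == IMPORT:
            c += 1
        else:
            d += 1
    if n_rows == 0:
        raise ValueError("empty rating table")
    return RatingContingency(a=a, b=b, c=c, d=d)


def expand_contingency(ct: RatingContingency) -> list[tuple[str, str, str]]:
    """A rating table that tabulates back to ``ct`` (inverse construction)."""
    rows: list[tuple[str, str, str]] = []
    cells = (
        (ct.a, IMPORT, IMPORT),
        (ct.b, IMPORT, NON_IMPORT),
        (ct.c, NON_IMPORT, IMPORT),
        (ct.d, NON_IMPORT, NON_IMPORT),
    )
    i = 0
    for count, d1, d2 in cells:
        for _ in range(count):
            i += 1
            rows.append((f"u{i:04d}", d1, d2))
    return rows


def read_rating_table(path: str | Path) -> list[tuple[str, str, str]]:
    """TSV with columns unit_id, rater1, rater2; an optional header row
    named exactly that is skipped."""
    rows: list[tuple[str, str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[:3] == ["unit_id", "rater1", "rater2"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            rows.append((parts[0], parts[1], parts[2]))
    return rows


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as printed statistics convention."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def import_rate_pct(n_import: int, n_total: int, decimals: int) -> float:
    """Approval percentage truncated (not rounded) to ``decimals`` places,
    matching the truncation convention of the reported rates
    (e.g. 42/55 -> 76.3)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    scale = 10**decimals
    return math.floor(100.0 * n_import / n_total * scale) / scale
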