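"""Disproportionality statistics: 2x2 tables, PRR, chi-square, Evans criteria.

For one drug entity, one Preferred Term (PT) and one stratum of a report set,
the 2x2 contingency table is

    ============  ========  ===========
                  with PT   without PT
    ============  ========  ===========
    with entity      a          b
    without          c          d
    ============  ========  ===========

The proportional reporting ratio is PRR = [a/(a+b)] / [c/(c+d)]: the PT's
reporting rate among the entity's reports relative to its rate in the
background (all other reports in the stratum).  PRR = 2 means the event is
reported twice as frequently under the drug as in the background.

A positive signal of disproportionality follows the Evans criteria:
PRR >= 2, chi-square >= 4, and at least 3 cases (the a cell), all thresholds
inclusive.  Whether the chi-square carries the Yates continuity correction is
an explicit, recorded choice (default: corrected), since it moves values near
the chi2 = 4 boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import AgeStratum, ReportSet, ValidationError
from .meddra import Category, DrugEntity


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero marginal: the statistic is undefined."""


class UndefinedRateError(ValueError):
    """PRR requested for an entity with no reports in the stratum (a+b = 0)."""


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency counts a/b/c/d for one (entity, PT, stratum)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"cell {name} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """Row and column sums (a+b, c+d, a+c, b+d)."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class SignalThresholds:
    """Evans signal criteria thresholds, all compared inclusively."""

    prr_min: float = 2.0
    chi2_min: float = 4.0
    n_min: int = 3

    def __post_init__(self) -> None:
        if self.prr_min <= 0 or self.chi2_min <= 0 or self.n_min <= 0:
            raise ValidationError("signal thresholds must be positive")


def build_contingency(
    rs: ReportSet,
    entity: DrugEntity,
    pt: str,
    stratum: AgeStratum = AgeStratum.OVERALL,
) -> TwoByTwo:
    """Count the 2x2 table for (entity, pt) within one stratum of ``rs``.

    A report is "with entity" when its drug set intersects the entity's
    members, "with pt" when the (case-folded) PT is in its PT set; the stratum
    restricts to reports whose assigned age group equals it (OVERALL imposes
    no restriction, so unknown-age reports participate only there).

    Raises :class:`DegenerateTableError` for an empty stratum.
    """
    folded_pt = str(pt).strip().casefold()
    a = b = c = d = 0
    for r in rs:
        if stratum is not AgeStratum.OVERALL and r.age_group is not stratum:
            continue
        exposed = entity.matches(r.drugs)
        has_pt = any(p.casefold() == folded_pt for p in r.pts)
        if exposed:
            if has_pt:
                a += 1
            else:
                b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise DegenerateTableError(
            f"empty stratum {stratum.value!r} for entity {entity.name!r}"
        )
    return TwoByTwo(a, b, c, d)


def prr(t: TwoByTwo) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    Conventions at the boundaries keep the statistic faithful to its
    definition (no Haldane-style 0.5 correction): a = 0 gives 0; c = 0 with
    a > 0 gives +infinity; an empty background (c+d = 0) is undefined (NaN);
    a+b = 0 raises :class:`UndefinedRateError`.
    """
    if t.a + t.b == 0:
        raise UndefinedRateError("entity has no reports in stratum (a+b = 0)")
    if t.c + t.d == 0:
        return math.nan
    if t.a == 0:
        return 0.0
    if t.c == 0:
        return math.inf
    return (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))


def chi_square(t: TwoByTwo, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table, optionally Yates-corrected.

    Uncorrected: N(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)] with N the table
    total; the Yates variant replaces |ad - bc| by max(0, |ad - bc| - N/2).
    Raises :class:`DegenerateTableError` when any marginal is zero.
    """
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("zero marginal: chi-square undefined")
    n = t.n_total
    cross = t.a * t.d - t.b * t.c
    if yates:
        adj = abs(cross) - n / 2.0
        if adj <= 0:
            return 0.0
        num = n * adj * adj
    else:
        num = n * float(cross) * float(cross)
    return num / (float(r1) * r2 * c1 * c2)


@dataclass(frozen=True)
class SignalResult:
    """Outcome of one disproportionality analysis.

    ``n`` equals the a cell.  ``degenerate`` marks analyses whose statistics
    are undefined (empty stratum, zero marginal, or no exposed reports);
    these are carried as non-signals so one empty cell cannot abort a screen.
    """

    entity: str
    pt: str
    stratum: AgeStratum
    n: int
    prr: float
    chi2: float
    is_signal: bool
    category: Category | None = None
    degenerate: bool = False
    yates: bool = True


def _meets(value: float, minimum: float) -> bool:
    # NaN comparisons are False, so undefined statistics can never signal.
    return value >= minimum


def evaluate_signal(
    t: TwoByTwo | None,
    thresholds: SignalThresholds = SignalThresholds(),
    yates: bool = True,
    *,
    entity: str = "",
    pt: str = "",
    stratum: AgeStratum = AgeStratum.OVERALL,
    category: Category | None = None,
) -> SignalResult:
    """Apply the Evans criteria to one table.

    All three thresholds are inclusive ("at least"); an infinite PRR with
    enough cases and a large enough chi-square is a signal.  Degenerate
    tables (or ``t is None`` for an empty stratum) yield a flagged non-signal
    with NaN statistics rather than raising.
    """
    if t is None:
        return SignalResult(entity, pt, stratum, 0, math.nan, math.nan,
                            False, category, degenerate=True, yates=yates)
    try:
        prr_value = prr(t)
    except UndefinedRateError:
        prr_value = math.nan
    try:
        chi2_value = chi_square(t, yates=yates)
    except DegenerateTableError:
        chi2_value = math.nan
    degenerate = math.isnan(prr_value) or math.isnan(chi2_value)
    flag = (
        t.a >= thresholds.n_min
        and _meets(prr_value, thresholds.prr_min)
        and _meets(chi2_value, thresholds.chi2_min)
    )
    return SignalResult(
        entity=entity,
        pt=pt,
        stratum=stratum,
        n=t.a,
        prr=prr_value,
        chi2=chi2_value,
        is_signal=bool(flag),
        category=category,
        degenerate=degenerate,
        yates=yates,
    )
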