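"""Stratified disproportionality screen across drug entities, PTs and age strata.

:func:`run_screen` enumerates every (entity, PT, stratum) triple of a
:class:`ScreenPlan` exactly once, computes its 2x2 table against the
stratum-restricted background and applies the Evans criteria, emitting one
:class:`~prrscreen.stats.SignalResult` per triple in deterministic
(entity, category, PT, stratum) order.  Counting is vectorized internally but
agrees cell-for-cell with :func:`~prrscreen.stats.build_contingency`.

Output shaping mirrors common pharmacovigilance reporting practice: a
demography table (report counts and percentages by age band per entity), a
per-entity signal table retaining only criteria-passing cells (suppressed
cells rendered as "-"), and a cross-entity comparison ranking signal strength
for PTs that signal in two or more individual drugs.

No multiple-testing adjustment is applied: every analysis is reported at its
nominal thresholds, as is conventional for hypothesis-generating screens of
spontaneous-report data.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AGE_STRATA,
    SCREEN_STRATA,
    AgeStratum,
    ReportSet,
    ValidationError,
)
from .meddra import Category, DrugEntity, PTDictionary, category_order
from .stats import SignalResult, SignalThresholds, TwoByTwo, evaluate_signal

logger = logging.getLogger(__name__)

DASH = "-"


@dataclass(frozen=True)
class AnalysisCounts:
    """Breakdown of how many disproportionality analyses a screen performs."""

    class_overall: int
    per_statin_overall: int
    stratified: int

    @property
    def total(self) -> int:
        return self.class_overall + self.per_statin_overall + self.stratified


def count_analyses(n_pts: int, n_statins: int, n_strata: int) -> AnalysisCounts:
    """Analysis-count combinatorics of a full screen.

    ``class_overall`` analyses test every PT against the pooled class in the
    whole population; ``per_statin_overall`` repeats that per individual
    statin; ``stratified`` re-runs all (1 + n_statins) entities for every PT
    within each of the ``n_strata`` age bands.
    """
    for name, v in (("n_pts", n_pts), ("n_statins", n_statins),
                    ("n_strata", n_strata)):
        if int(v) != v or v < 1:
            raise ValidationError(f"{name} must be a positive integer, got {v!r}")
    n_pts, n_statins, n_strata = int(n_pts), int(n_statins), int(n_strata)
    return AnalysisCounts(
        class_overall=n_pts,
        per_statin_overall=n_pts * n_statins,
        stratified=n_pts * (1 + n_statins) * n_strata,
    )


@dataclass(frozen=True)
class ScreenPlan:
    """Everything a screen needs: entities, PT vocabulary, strata, thresholds
    and the chi-square variant.  The plan enumerates every (entity, pt,
    stratum) triple exactly once."""

    entities: tuple[DrugEntity, ...]
    pt_dict: PTDictionary
    strata: tuple[AgeStratum, ...] = SCREEN_STRATA
    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    yates: bool = True

    def __post_init__(self) -> None:
        entities = tuple(self.entities)
        if not entities:
            raise ValidationError("a ScreenPlan needs at least one entity")
        names = [e.name for e in entities]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate entity names in plan")
        object.__setattr__(self, "entities", entities)
        object.__setattr__(self, "strata", tuple(self.strata))

    @property
    def n_analyses(self) -> int:
        return len(self.entities) * len(self.pt_dict) * len(self.strata)


def _stratum_codes(reports) -> np.ndarray:
    code = {s: i for i, s in enumerate(AGE_STRATA)}
    code[AgeStratum.UNKNOWN] = len(AGE_STRATA)
    return np.fromiter((code[r.age_group] for r in reports), dtype=np.int8,
                       count=len(reports))


def _indicators(
    rs: ReportSet, entities: Sequence[DrugEntity], pt_names: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean exposure and PT-occurrence matrices plus stratum codes."""
    n = len(rs)
    exposure = np.zeros((n, len(entities)), dtype=bool)
    occurrence = np.zeros((n, len(pt_names)), dtype=bool)
    pt_index = {p.casefold(): j for j, p in enumerate(pt_names)}
    members = [e.members for e in entities]
    for i, r in enumerate(rs.reports):
        drugs = r.drugs
        for k, ms in enumerate(members):
            if not ms.isdisjoint(drugs):
                exposure[i, k] = True
        for p in r.pts:
            j = pt_index.get(p.casefold())
            if j is not None:
                occurrence[i, j] = True
    return exposure, occurrence, _stratum_codes(rs.reports)


def run_screen(rs: ReportSet, plan: ScreenPlan) -> list[SignalResult]:
    """Run every analysis of the plan on a (pre-filtered) report set.

    Returns exactly ``plan.n_analyses`` results in deterministic (entity,
    category, PT, stratum) order.  Degenerate tables (empty stratum, entity
    with no reports in the stratum, zero marginal) become flagged non-signals
    and are logged, never raised.  Raises on an empty report set.
    """
    if len(rs) == 0:
        raise ValidationError("cannot screen an empty ReportSet")
    entities = plan.entities
    pt_names = plan.pt_dict.pts
    exposure, occurrence, codes = _indicators(rs, entities, pt_names)
    stratum_code = {s: i for i, s in enumerate(AGE_STRATA)}

    # Per-stratum marginals and the a-cell matrix (entities x PTs).
    per_stratum: dict[AgeStratum, tuple | None] = {}
    for stratum in plan.strata:
        if stratum is AgeStratum.OVERALL:
            mask = slice(None)
            n_in = len(rs)
        else:
            mask = codes == stratum_code[stratum]
            n_in = int(mask.sum())
        if n_in == 0:
            per_stratum[stratum] = None
            continue
        exp_s = exposure[mask]
        occ_s = occurrence[mask]
        a_mat = exp_s.T.astype(np.int64) @ occ_s
        per_stratum[stratum] = (
            a_mat,
            exp_s.sum(axis=0, dtype=np.int64),
            occ_s.sum(axis=0, dtype=np.int64),
            n_in,
        )

    categories = {p: plan.pt_dict.classify(p) for p in pt_names}
    results: list[SignalResult] = []
    for k, entity in enumerate(entities):
        for j, pt in enumerate(pt_names):
            for stratum in plan.strata:
                cell = per_stratum[stratum]
                if cell is None:
                    res = evaluate_signal(
                        None, plan.thresholds, plan.yates,
                        entity=entity.name, pt=pt, stratum=stratum,
                        category=categories[pt],
                    )
                else:
                    a_mat, n_exposed, n_with_pt, n_in = cell
                    a = int(a_mat[k, j])
                    b = int(n_exposed[k]) - a
                    c = int(n_with_pt[j]) - a
                    d = n_in - int(n_exposed[k]) - int(n_with_pt[j]) + a
                    res = evaluate_signal(
                        TwoByTwo(a, b, c, d), plan.thresholds, plan.yates,
                        entity=entity.name, pt=pt, stratum=stratum,
                        category=categories[pt],
                    )
                if res.degenerate:
                    logger.info(
                        "degenerate contingency table: entity=%r pt=%r stratum=%s",
                        entity.name, pt, stratum.value,
                    )
                results.append(res)
    return results


def demography_table(
    rs: ReportSet, entities: Iterable[DrugEntity]
) -> pd.DataFrame:
    """Report counts and age-band percentages per entity.

    Percentages are stratum count / overall entity count x 100, rounded to
    two decimals; unknown-age reports are inside the overall count but have
    no band, so the four band percentages sum to less than 100 whenever ages
    are missing.  An entity with zero reports yields a zero row with a
    logged warning.
    """
    rows = []
    for entity in entities:
        counts = {s: 0 for s in AGE_STRATA}
        overall = 0
        for r in rs:
            if entity.matches(r.drugs):
                overall += 1
                group = r.age_group
                if group in counts:
                    counts[group] += 1
        if overall == 0:
            logger.warning("entity %r has zero reports", entity.name)
        row: dict[str, object] = {"entity": entity.name, "n_overall": overall}
        for stratum in AGE_STRATA:
            label = stratum.value.replace("-", "_").replace("+", "_plus")
            row[f"n_{label}"] = counts[stratum]
            row[f"pct_{label}"] = (
                round(100.0 * counts[stratum] / overall, 2) if overall else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(value: float, digits: int = 2) -> str:
    if math.isnan(value):
        return DASH
    if math.isinf(value):
        return "inf"
    return f"{value:.{digits}f}"


def signal_table(results: Iterable[SignalResult], entity: str) -> pd.DataFrame:
    """Per-entity grid of signalling cells only.

    One row per PT with at least one positive signal for the entity; each
    stratum contributes N / PRR / chi2 columns, with non-signalling cells
    rendered as "-".  Rows are ordered by the fixed category sequence, then
    by descending overall PRR (PTs signalling only within an age band come
    after, alphabetically).
    """
    by_pt: dict[str, dict[AgeStratum, SignalResult]] = {}
    cats: dict[str, Category | None] = {}
    for res in results:
        if res.entity != entity or not res.is_signal:
            continue
        by_pt.setdefault(res.pt, {})[res.stratum] = res
        cats[res.pt] = res.category

    def sort_key(pt: str):
        cat = cats[pt]
        cat_idx = category_order(cat) if cat is not None else len(Category)
        overall = by_pt[pt].get(AgeStratum.OVERALL)
        overall_prr = -overall.prr if overall is not None else math.inf
        return (cat_idx, overall_prr, pt.casefold())

    rows = []
    for pt in sorted(by_pt, key=sort_key):
        cat = cats[pt]
        row: dict[str, object] = {
            "category": cat.value if cat is not None else "",
            "pt": pt,
        }
        for stratum in SCREEN_STRATA:
            label = stratum.value.replace("-", "_").replace("+", "_plus")
            res = by_pt[pt].get(stratum)
            row[f"n_{label}"] = str(res.n) if res else DASH
            row[f"prr_{label}"] = _fmt(res.prr) if res else DASH
            row[f"chi2_{label}"] = _fmt(res.chi2) if res else DASH
        rows.append(row)
    columns = ["category", "pt"]
    for stratum in SCREEN_STRATA:
        label = stratum.value.replace("-", "_").replace("+", "_plus")
        columns += [f"n_{label}", f"prr_{label}", f"chi2_{label}"]
    return pd.DataFrame(rows, columns=columns)


def compare_across_entities(
    results: Iterable[SignalResult],
    class_entity: str | None = None,
) -> pd.DataFrame:
    """Cross-drug signal-strength comparison.

    Keeps every (stratum, PT) pair where two or more individual entities
    signal (a pooled-class entity named by ``class_entity`` is excluded from
    the ranking), lists each signalling entity's PRR, and marks the entity
    (or entities, on an exact tie) with the maximal PRR as strongest.
    """
    entity_order: list[str] = []
    flagged: dict[tuple[AgeStratum, str], dict[str, float]] = {}
    for res in results:
        if res.entity == class_entity:
            continue
        if res.entity not in entity_order:
            entity_order.append(res.entity)
        if res.is_signal:
            flagged.setdefault((res.stratum, res.pt), {})[res.entity] = res.prr

    stratum_rank = {s: i for i, s in enumerate(SCREEN_STRATA)}
    rows = []
    for (stratum, pt) in sorted(
        flagged, key=lambda key: (stratum_rank.get(key[0], 99), key[1].casefold())
    ):
        prrs = flagged[(stratum, pt)]
        if len(prrs) < 2:
            continue
        best = max(prrs.values())
        strongest = sorted(name for name, v in prrs.items() if v == best)
        row: dict[str, object] = {"stratum": stratum.value, "pt": pt}
        for name in entity_order:
            row[name] = _fmt(prrs[name]) if name in prrs else DASH
        row["strongest"] = "; ".join(strongest)
        rows.append(row)
    columns = ["stratum", "pt", *entity_order, "strongest"]
    return pd.DataFrame(rows, columns=columns)


def results_to_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Flatten screen results to a tidy table (full precision, one analysis
    per row), suitable for saving and later comparison runs."""
    rows = [
        {
            "entity": r.entity,
            "category": r.category.value if r.category is not None else "",
            "pt": r.pt,
            "stratum": r.stratum.value,
            "n": r.n,
            "prr": r.prr,
            "chi2": r.chi2,
            "is_signal": r.is_signal,
            "degenerate": r.degenerate,
            "yates": r.yates,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["entity", "category", "pt", "stratum", "n", "prr", "chi2",
                 "is_signal", "degenerate", "yates"],
    )


_STRATUM_BY_VALUE = {s.value: s for s in AgeStratum}
_CATEGORY_BY_VALUE = {c.value: c for c in Category}


def results_from_frame(df: pd.DataFrame) -> list[SignalResult]:
    """Inverse of :func:`results_to_frame`."""
    results = []
    for row in df.itertuples(index=False):
        results.append(
            SignalResult(
                entity=str(row.entity),
                pt=str(row.pt),
                stratum=_STRATUM_BY_VALUE[str(row.stratum)],
                n=int(row.n),
                prr=float(row.prr),
                chi2=float(row.chi2),
                is_signal=bool(row.is_signal),
                category=_CATEGORY_BY_VALUE.get(str(row.category)),
                degenerate=bool(row.degenerate),
                yates=bool(row.yates),
            )
        )
    return results
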