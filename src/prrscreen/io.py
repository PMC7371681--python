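"""Loading, cleaning and filtering of spontaneous adverse-event report tables.

The canonical on-disk form is three linked UTF-8 delimited-text tables sharing a
report-ID column, mirroring the demographic / drug / reaction split used by
spontaneous-report databases:

* ``DEMO(report_id, age_years, sex)`` — one row per report; ``sex`` coded
  ``F`` / ``M`` / empty; ``age_years`` empty when unknown, otherwise a number
  already expressed in years (age-unit codes such as decades or months are out
  of scope: convert before loading).
* ``DRUG(report_id, drugname)`` — one row per reported drug, verbatim names.
* ``REAC(report_id, pt)`` — one row per reported MedDRA Preferred Term.

Loading produces an immutable :class:`ReportSet` of :class:`AEReport` records:
one record per distinct report ID, with drug names canonicalized through a
:class:`DrugLexicon` and drug/PT multiplicities collapsed to sets (a report
counts at most once for any drug–event pair, the counting unit of
disproportionality analysis).  Filters return new subsets and never mutate.
"""

from __future__ import annotations

import enum
import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

DEMO_COLUMNS = ("report_id", "age_years", "sex")
DRUG_COLUMNS = ("report_id", "drugname")
REAC_COLUMNS = ("report_id", "pt")

AGE_MAX = 120.0


class FormatError(ValueError):
    """A delimited input table does not match the canonical format."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, emptiness, uniqueness)."""


class Sex(enum.Enum):
    FEMALE = "F"
    MALE = "M"
    UNKNOWN = ""


def parse_sex(raw: str | None) -> Sex:
    """Map an on-disk sex code to :class:`Sex`; anything unrecognized is unknown."""
    if raw is None:
        return Sex.UNKNOWN
    code = str(raw).strip().upper()
    if code == "F":
        return Sex.FEMALE
    if code == "M":
        return Sex.MALE
    return Sex.UNKNOWN


class AgeStratum(enum.Enum):
    """Age bands used for subgroup screening, chosen to track distinct female
    physiological phases, plus the unknown-age bucket and the OVERALL
    pseudo-stratum (no age restriction)."""

    S_0_18 = "0-18"
    S_19_39 = "19-39"
    S_40_59 = "40-59"
    S_60_PLUS = "60+"
    UNKNOWN = "unknown"
    OVERALL = "overall"


#: The four named age bands; together with UNKNOWN they partition any report set.
AGE_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum.S_0_18,
    AgeStratum.S_19_39,
    AgeStratum.S_40_59,
    AgeStratum.S_60_PLUS,
)

#: Default stratum sequence of a screen: the whole population, then each band.
SCREEN_STRATA: tuple[AgeStratum, ...] = (AgeStratum.OVERALL,) + AGE_STRATA


def assign_age_group(age_years: float | int | None) -> AgeStratum:
    """Assign an age in years to its stratum.

    Ages are truncated to completed years before binning so the closed
    intervals 0–18, 19–39, 40–59, ≥60 tile all real ages (18.9 years is 18
    completed years, hence the 0–18 band).  ``None``/NaN maps to UNKNOWN.
    """
    if age_years is None:
        return AgeStratum.UNKNOWN
    age = float(age_years)
    if math.isnan(age):
        return AgeStratum.UNKNOWN
    if age < 0 or age > AGE_MAX:
        raise ValidationError(f"age_years out of range [0, {AGE_MAX:g}]: {age!r}")
    completed = math.floor(age)
    if completed <= 18:
        return AgeStratum.S_0_18
    if completed <= 39:
        return AgeStratum.S_19_39
    if completed <= 59:
        return AgeStratum.S_40_59
    return AgeStratum.S_60_PLUS


@dataclass(frozen=True)
class AEReport:
    """One spontaneous report: an opaque ID, patient sex and age, and the sets
    of canonical drug names and MedDRA Preferred Terms it mentions."""

    report_id: str
    sex: Sex
    age_years: float | None
    drugs: frozenset[str]
    pts: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        object.__setattr__(self, "pts", frozenset(self.pts))
        age = self.age_years
        if age is not None:
            age = float(age)
            if math.isnan(age):
                age = None
            elif age < 0 or age > AGE_MAX:
                raise ValidationError(
                    f"report {self.report_id}: age_years out of range: {age!r}"
                )
            object.__setattr__(self, "age_years", age)

    @property
    def age_group(self) -> AgeStratum:
        return assign_age_group(self.age_years)


@dataclass(frozen=True)
class DrugLexicon:
    """Synonym table mapping case-folded verbatim drug names (brand names,
    abbreviations, misspellings …) to canonical drug names."""

    synonym_to_canonical: Mapping[str, str]
    canonical_names: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        mapping = {
            str(k).strip().casefold(): str(v).strip().casefold()
            for k, v in self.synonym_to_canonical.items()
        }
        canon = frozenset(mapping.values()) | frozenset(
            str(c).strip().casefold() for c in self.canonical_names
        )
        object.__setattr__(self, "synonym_to_canonical", mapping)
        object.__setattr__(self, "canonical_names", canon)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DrugLexicon":
        return cls(dict(pairs))

    @classmethod
    def from_csv(cls, path, delimiter: str = ",") -> "DrugLexicon":
        """Read a two-column (synonym, canonical) table with a header row."""
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                         comment="#")
        if df.shape[1] < 2:
            raise FormatError(f"{path}: lexicon needs two columns (synonym, canonical)")
        syn, canon = df.columns[0], df.columns[1]
        return cls(dict(zip(df[syn], df[canon])))


#: Lexicon that maps nothing: every lookup is an unmapped verbatim miss.
EMPTY_LEXICON = DrugLexicon({})


def canonicalize_drug(name: str, lexicon: DrugLexicon) -> tuple[str, bool]:
    """Case-fold and trim a verbatim drug name and look it up in the lexicon.

    Returns ``(canonical_name, True)`` on a hit and ``(folded_verbatim, False)``
    on a miss; unmapped names are kept rather than dropped so that background
    counts reflect the whole extract.
    """
    folded = str(name).strip().casefold()
    if not folded:
        raise ValidationError("empty drug name")
    canonical = lexicon.synonym_to_canonical.get(folded)
    if canonical is not None:
        return canonical, True
    return folded, False


class ReportSet:
    """An immutable collection of :class:`AEReport` with unique report IDs.

    ``provenance`` is a free-text trail of source files and filters applied;
    filtering operations return new subsets carrying an extended trail.
    """

    __slots__ = ("reports", "provenance")

    def __init__(self, reports: Iterable[AEReport], provenance: str = "") -> None:
        reports = tuple(reports)
        ids = {r.report_id for r in reports}
        if len(ids) != len(reports):
            raise ValidationError("duplicate report_id within a ReportSet")
        self.reports = reports
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return frozenset(self.reports) == frozenset(other.reports)

    def __hash__(self):  # pragma: no cover - sets of ReportSets unused
        return hash(frozenset(self.reports))

    def filter_female(self) -> "ReportSet":
        """Restrict to female patients; unknown-sex reports are excluded.
        Idempotent: filtering an all-female set returns an equal set."""
        kept = [r for r in self.reports if r.sex is Sex.FEMALE]
        return ReportSet(kept, provenance=_extend(self.provenance, "filtered sex=F"))

    def filter_stratum(self, stratum: AgeStratum) -> "ReportSet":
        """Restrict to one age stratum (OVERALL returns everything)."""
        if stratum is AgeStratum.OVERALL:
            return self
        kept = [r for r in self.reports if r.age_group is stratum]
        return ReportSet(
            kept, provenance=_extend(self.provenance, f"stratum={stratum.value}")
        )

    def stratum_counts(self) -> dict[AgeStratum, int]:
        """Report counts per age stratum, including UNKNOWN and OVERALL.
        The five disjoint buckets always sum to the OVERALL count."""
        counts = {s: 0 for s in AGE_STRATA}
        counts[AgeStratum.UNKNOWN] = 0
        for r in self.reports:
            counts[r.age_group] += 1
        counts[AgeStratum.OVERALL] = len(self.reports)
        return counts


def _extend(provenance: str, step: str) -> str:
    return f"{provenance}; {step}" if provenance else step


def filter_female(rs: ReportSet) -> ReportSet:
    """Module-level alias of :meth:`ReportSet.filter_female`."""
    return rs.filter_female()


def _read_table(path, required: tuple[str, ...], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def _parse_age(raw: str, report_id: str) -> float | None:
    text = raw.strip()
    if not text:
        return None
    try:
        age = float(text)
    except ValueError:
        raise FormatError(
            f"report {report_id}: unparsable age_years value {raw!r}"
        ) from None
    if age < 0 or age > AGE_MAX:
        raise ValidationError(f"report {report_id}: age_years out of range: {age!r}")
    return age


def load_reports(
    demo_path,
    drug_path,
    reac_path,
    lexicon: DrugLexicon | None = None,
    delimiter: str = ",",
) -> ReportSet:
    """Load the three canonical tables into a :class:`ReportSet`.

    One :class:`AEReport` is built per distinct demographics row; reports with
    no drug or reaction rows keep empty sets.  Drug names are canonicalized
    through ``lexicon`` (misses kept verbatim, case-folded, counted in the
    provenance).  Drug/reaction rows whose report ID has no demographics row
    are dropped with a warning and counted in the provenance; exact duplicate
    rows collapse silently (set semantics).
    """
    lexicon = lexicon if lexicon is not None else EMPTY_LEXICON

    demo = _read_table(demo_path, DEMO_COLUMNS, delimiter).drop_duplicates()
    dup_ids = demo["report_id"][demo["report_id"].duplicated()].unique()
    if len(dup_ids):
        raise FormatError(
            f"{demo_path}: conflicting demographics rows for report_id(s): "
            + ", ".join(map(str, dup_ids[:5]))
        )
    known_ids = set(demo["report_id"])

    drug = _read_table(drug_path, DRUG_COLUMNS, delimiter)
    reac = _read_table(reac_path, REAC_COLUMNS, delimiter)

    dropped_drug = int((~drug["report_id"].isin(known_ids)).sum())
    dropped_reac = int((~reac["report_id"].isin(known_ids)).sum())
    if dropped_drug:
        logger.warning(
            "%s: dropped %d drug row(s) with report_id absent from demographics",
            drug_path, dropped_drug,
        )
    if dropped_reac:
        logger.warning(
            "%s: dropped %d reaction row(s) with report_id absent from demographics",
            reac_path, dropped_reac,
        )
    drug = drug[drug["report_id"].isin(known_ids)]
    reac = reac[reac["report_id"].isin(known_ids)]

    drugs_by_id: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for rid, name in zip(drug["report_id"], drug["drugname"]):
        if not str(name).strip():
            continue
        canonical, mapped = canonicalize_drug(name, lexicon)
        if not mapped:
            unmapped.add(canonical)
        drugs_by_id.setdefault(rid, set()).add(canonical)

    pts_by_id: dict[str, set[str]] = {}
    seen_folded: dict[str, set[str]] = {}
    for rid, pt in zip(reac["report_id"], reac["pt"]):
        text = str(pt).strip()
        if not text:
            continue
        folded = text.casefold()
        if folded in seen_folded.setdefault(rid, set()):
            continue
        seen_folded[rid].add(folded)
        pts_by_id.setdefault(rid, set()).add(text)

    reports = []
    for rid, age_raw, sex_raw in zip(
        demo["report_id"], demo["age_years"], demo["sex"]
    ):
        reports.append(
            AEReport(
                report_id=str(rid),
                sex=parse_sex(sex_raw),
                age_years=_parse_age(str(age_raw), str(rid)),
                drugs=frozenset(drugs_by_id.get(rid, ())),
                pts=frozenset(pts_by_id.get(rid, ())),
            )
        )

    provenance = (
        f"loaded demo={demo_path} drug={drug_path} reac={reac_path} "
        f"(delimiter={delimiter!r}); {len(reports)} reports; "
        f"dropped {dropped_drug} orphan drug row(s), {dropped_reac} orphan "
        f"reaction row(s); {len(unmapped)} unmapped drug name(s) kept verbatim"
    )
    return ReportSet(reports, provenance=provenance)


def _format_age(age: float | None) -> str:
    if age is None:
        return ""
    return str(int(age)) if float(age).is_integer() else repr(float(age))


def write_reports(
    rs: ReportSet, demo_path, drug_path, reac_path, delimiter: str = ","
) -> None:
    """Write a :class:`ReportSet` back to the three canonical tables.

    Output is deterministic (rows sorted by report ID, then name) and
    round-trips: reloading with an empty lexicon yields an equal set, because
    stored drug names are already case-folded.
    """
    reports = sorted(rs.reports, key=lambda r: r.report_id)
    demo = pd.DataFrame(
        {
            "report_id": [r.report_id for r in reports],
            "age_years": [_format_age(r.age_years) for r in reports],
            "sex": [r.sex.value for r in reports],
        }
    )
    drug_rows = [
        (r.report_id, d) for r in reports for d in sorted(r.drugs)
    ]
    reac_rows = [
        (r.report_id, p) for r in reports for p in sorted(r.pts)
    ]
    demo.to_csv(demo_path, sep=delimiter, index=False)
    pd.DataFrame(drug_rows, columns=list(DRUG_COLUMNS)).to_csv(
        drug_path, sep=delimiter, index=False
    )
    pd.DataFrame(reac_rows, columns=list(REAC_COLUMNS)).to_csv(
        reac_path, sep=delimiter, index=False
    )
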