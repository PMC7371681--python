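"""Ovary/uterus adverse-event vocabulary and drug-entity resolution.

Adverse events are coded as MedDRA Preferred Terms (PTs).  The screen works
from a :class:`PTDictionary` assigning each PT to exactly one of ten fixed
categories of ovary- and uterus-related disorders (a closed set derived from
the MedDRA structural hierarchy).  A partial working vocabulary is bundled as
``data/ovary_uterus_pts.csv``; a complete user-supplied dictionary can be
loaded from any two-column (pt, category) delimited file.

Drug entities are the units being screened: each individual statin as a
singleton, plus the pooled "statins as a class" entity whose member set is the
union of the seven statins.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import DrugLexicon, FormatError


class Category(enum.Enum):
    """The ten ovary/uterus disorder categories (closed set).

    Enum definition order fixes the category ordering of all output tables.
    """

    OVARIAN_CYSTS_AND_NEOPLASMS = "ovarian cysts and neoplasms"
    UTERINE_NEOPLASMS = "uterine neoplasms"
    CERVIX_NEOPLASMS = "cervix neoplasms"
    OVARIAN_DISORDERS = "ovarian disorders (excl cysts and neoplasms)"
    UTERINE_DISORDERS = "uterine disorders (excl neoplasms)"
    CERVIX_DISORDERS = "cervix disorders (excl neoplasms)"
    ENDOCRINE_DISORDERS_OF_GONADAL_FUNCTION = "endocrine disorders of gonadal function"
    MENSTRUAL_CYCLE_AND_UTERINE_BLEEDING_DISORDERS = (
        "menstrual cycle and uterine bleeding disorders"
    )
    MENOPAUSE_RELATED_CONDITIONS = "menopause related conditions"
    SEXUAL_FUNCTION_DISORDERS = "sexual function disorders"


_CATEGORY_BY_LABEL = {c.value.casefold(): c for c in Category}
_CATEGORY_INDEX = {c: i for i, c in enumerate(Category)}


def category_order(category: Category) -> int:
    """Stable sort key for the fixed category sequence of output tables."""
    return _CATEGORY_INDEX[category]


@dataclass(frozen=True)
class PTDictionary:
    """Mapping from MedDRA Preferred Term to its ovary/uterus category.

    Lookup is exact after case-folding; no lower-level-term rollup or
    hierarchy traversal is attempted (the screen operates purely at PT level).
    """

    pt_to_category: Mapping[str, Category]

    def __post_init__(self) -> None:
        display: dict[str, str] = {}
        mapping: dict[str, Category] = {}
        for pt, cat in self.pt_to_category.items():
            if not isinstance(cat, Category):
                raise FormatError(f"not a known category: {cat!r}")
            folded = str(pt).strip().casefold()
            if folded in mapping and mapping[folded] is not cat:
                raise FormatError(
                    f"PT {pt!r} mapped to two categories: "
                    f"{mapping[folded].value!r} and {cat.value!r}"
                )
            mapping[folded] = cat
            display.setdefault(folded, str(pt).strip())
        object.__setattr__(self, "pt_to_category", mapping)
        object.__setattr__(self, "_display", display)

    def classify(self, pt: str) -> Category | None:
        """Category of a PT, or ``None`` when out of vocabulary."""
        return self.pt_to_category.get(str(pt).strip().casefold())

    @property
    def pts(self) -> tuple[str, ...]:
        """PT display names in deterministic order: category, then name."""
        return tuple(
            sorted(
                self._display.values(),
                key=lambda p: (category_order(self.classify(p)), p.casefold()),
            )
        )

    @property
    def categories(self) -> frozenset[Category]:
        return frozenset(self.pt_to_category.values())

    def __len__(self) -> int:
        return len(self.pt_to_category)

    def __contains__(self, pt: str) -> bool:
        return self.classify(pt) is not None

    def subset(self, pts: Iterable[str]) -> "PTDictionary":
        """Dictionary restricted to the given PTs (unknown names ignored)."""
        keep = {}
        for pt in pts:
            cat = self.classify(pt)
            if cat is not None:
                keep[str(pt).strip()] = cat
        return PTDictionary(keep)


def classify_pt(pt: str, dictionary: PTDictionary) -> Category | None:
    """Module-level alias of :meth:`PTDictionary.classify`."""
    return dictionary.classify(pt)


def load_pt_dictionary(path, delimiter: str = ",") -> PTDictionary:
    """Load a two-column (pt, category) delimited file into a dictionary.

    Category strings are validated against the closed ten-value set; an
    unknown category or a PT repeated with a conflicting category is a
    format error naming the offender.  Repeated consistent rows collapse.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     comment="#")
    required = ("pt", "category")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    mapping: dict[str, Category] = {}
    folded: dict[str, Category] = {}
    for i, (pt, cat_raw) in enumerate(zip(df["pt"], df["category"])):
        pt = str(pt).strip()
        if not pt:
            continue
        cat = _CATEGORY_BY_LABEL.get(str(cat_raw).strip().casefold())
        if cat is None:
            raise FormatError(
                f"{path}, row {i + 2}: unknown category {cat_raw!r} for PT {pt!r}"
            )
        prev = folded.get(pt.casefold())
        if prev is not None and prev is not cat:
            raise FormatError(
                f"{path}, row {i + 2}: PT {pt!r} already mapped to {prev.value!r}"
            )
        folded[pt.casefold()] = cat
        mapping[pt] = cat
    return PTDictionary(mapping)


def load_bundled_dictionary() -> PTDictionary:
    """Load the bundled partial ovary/uterus PT vocabulary."""
    ref = resources.files("prrscreen.data").joinpath("ovary_uterus_pts.csv")
    with resources.as_file(ref) as path:
        return load_pt_dictionary(path)


@dataclass(frozen=True)
class DrugEntity:
    """A screened drug unit: an individual drug (singleton member set) or a
    pooled class whose members are several canonical drug names.  A report is
    exposed to the entity when its drug set intersects the member set."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        members = frozenset(str(m).strip().casefold() for m in self.members)
        if not members:
            raise FormatError(f"entity {self.name!r} has no members")
        object.__setattr__(self, "members", members)

    def matches(self, drugs: Iterable[str]) -> bool:
        return not self.members.isdisjoint(drugs)


#: Canonical names of the seven statins, in the conventional reporting order.
STATIN_NAMES: tuple[str, ...] = (
    "atorvastatin",
    "simvastatin",
    "rosuvastatin",
    "pravastatin",
    "lovastatin",
    "fluvastatin",
    "pitavastatin",
)

CLASS_ENTITY_NAME = "statins as a class"


def default_statin_entities() -> list[DrugEntity]:
    """The eight default screen entities: the pooled statin class first, then
    the seven individual statins as singletons."""
    entities = [DrugEntity(CLASS_ENTITY_NAME, frozenset(STATIN_NAMES))]
    entities.extend(DrugEntity(name, frozenset({name})) for name in STATIN_NAMES)
    return entities


def default_statin_lexicon() -> DrugLexicon:
    """Identity entries for the seven statin generic names plus the common US
    brand names, for convenience when loading raw extracts."""
    pairs = [(name, name) for name in STATIN_NAMES]
    pairs += [
        ("lipitor", "atorvastatin"),
        ("zocor", "simvastatin"),
        ("crestor", "rosuvastatin"),
        ("pravachol", "pravastatin"),
        ("mevacor", "lovastatin"),
        ("altoprev", "lovastatin"),
        ("lescol", "fluvastatin"),
        ("livalo", "pitavastatin"),
    ]
    return DrugLexicon.from_pairs(pairs)
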