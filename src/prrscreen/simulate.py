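"""Synthetic spontaneous-report generator with injected disproportionality.

The generator emulates the structure of a female-only spontaneous-report
extract: multi-drug, multi-event reports; an age mix concentrated in the
40-59 and 60+ bands with a substantial missing-age fraction; background
reporting rates per drug and per Preferred Term (PT); and configurable
injected reporting-rate multipliers for chosen (drug, PT, age-stratum)
triples, recorded in a :class:`TruthLedger` for recovery testing.

Generative model
----------------
Each report draws, independently: an age stratum from the configured
distribution (with an integer age uniform inside the band, or missing); one
Bernoulli exposure per drug in the catalog; one Bernoulli occurrence per PT
in the catalog.  For reports exposed to an injected signal's drug and lying
in its stratum, that PT's occurrence probability is ``baseline x multiplier``
(capped at 1, with a warning).  A report that would end up with no drug (or
no PT) receives one catalog-weighted fill-in item, so every report mentions
at least one drug and one event, as real reports do.

Because PT occurrence is independent of drug exposure except through the
injected couplings, the PRR of every non-injected (drug, PT) pair is exactly
1 in expectation, and the PRR of an injected pair approaches its multiplier
when the baseline and the fill-in contribution are small.  The ledger stores
the exact expected PRR computed from the configured probabilities (including
the fill-in correction), so tests need not rely on the rare-event
approximation.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AGE_STRATA,
    AEReport,
    AgeStratum,
    ReportSet,
    Sex,
    ValidationError,
)
from .stats import SignalResult

logger = logging.getLogger(__name__)

#: Integer age range sampled within each band (inclusive bounds).
_AGE_RANGES: dict[AgeStratum, tuple[int, int]] = {
    AgeStratum.S_0_18: (0, 18),
    AgeStratum.S_19_39: (19, 39),
    AgeStratum.S_40_59: (40, 59),
    AgeStratum.S_60_PLUS: (60, 100),
}

#: Representative age used when constructing deterministic cohorts.
_REPRESENTATIVE_AGE: dict[AgeStratum, float | None] = {
    AgeStratum.S_0_18: 9.0,
    AgeStratum.S_19_39: 30.0,
    AgeStratum.S_40_59: 50.0,
    AgeStratum.S_60_PLUS: 70.0,
    AgeStratum.UNKNOWN: None,
}


@dataclass(frozen=True)
class InjectedSignal:
    """One planted association: within ``stratum`` (OVERALL = everywhere),
    reports exposed to ``drug`` report ``pt`` at baseline x ``multiplier``."""

    drug: str
    pt: str
    stratum: AgeStratum = AgeStratum.OVERALL
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValidationError("injected multiplier must be >= 1")
        object.__setattr__(self, "drug", str(self.drug).strip().casefold())
        object.__setattr__(self, "pt", str(self.pt).strip())


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic extract.

    ``drug_catalog`` and ``pt_catalog`` map names to per-report occurrence
    probabilities.  ``age_distribution`` gives probabilities for the four age
    bands plus the unknown-age fraction, summing to 1.  The optional
    ``drugs_per_report_mean`` / ``pts_per_report_mean`` rescale the catalog
    probabilities to a target expected count per report (the realized count
    is then Poisson-binomial with a minimum of one).
    """

    n_reports: int
    drug_catalog: Mapping[str, float]
    pt_catalog: Mapping[str, float]
    age_distribution: Mapping[AgeStratum, float]
    injected: tuple[InjectedSignal, ...] = ()
    seed: int = 0
    drugs_per_report_mean: float | None = None
    pts_per_report_mean: float | None = None

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValidationError("n_reports must be >= 1")
        drugs = {str(k).strip().casefold(): float(v)
                 for k, v in self.drug_catalog.items()}
        pts = {str(k).strip(): float(v) for k, v in self.pt_catalog.items()}
        for name, cat in (("drug_catalog", drugs), ("pt_catalog", pts)):
            if not cat:
                raise ValidationError(f"{name} must be non-empty")
            for k, p in cat.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(f"{name}[{k!r}] not a probability: {p}")
        ages = {s: float(self.age_distribution.get(s, 0.0))
                for s in (*AGE_STRATA, AgeStratum.UNKNOWN)}
        if any(p < 0 for p in ages.values()):
            raise ValidationError("age_distribution probabilities must be >= 0")
        if not math.isclose(sum(ages.values()), 1.0, abs_tol=1e-9):
            raise ValidationError("age_distribution must sum to 1")
        if not (0.0 <= ages[AgeStratum.UNKNOWN] < 1.0):
            raise ValidationError("missing-age fraction must be in [0, 1)")
        injected = tuple(self.injected)
        folded_pts = {p.casefold() for p in pts}
        for inj in injected:
            if inj.drug not in drugs:
                raise ValidationError(f"injected drug {inj.drug!r} not in catalog")
            if inj.pt.casefold() not in folded_pts:
                raise ValidationError(f"injected PT {inj.pt!r} not in catalog")
        object.__setattr__(self, "drug_catalog", drugs)
        object.__setattr__(self, "pt_catalog", pts)
        object.__setattr__(self, "age_distribution", ages)
        object.__setattr__(self, "injected", injected)

    # -- effective (possibly rescaled) probabilities ------------------------

    @property
    def drug_probs(self) -> dict[str, float]:
        return _rescale(self.drug_catalog, self.drugs_per_report_mean, "drug")

    @property
    def pt_probs(self) -> dict[str, float]:
        return _rescale(self.pt_catalog, self.pts_per_report_mean, "PT")


def _rescale(catalog: Mapping[str, float], mean: float | None,
             what: str) -> dict[str, float]:
    if mean is None:
        return dict(catalog)
    total = sum(catalog.values())
    if total <= 0:
        raise ValidationError(f"cannot rescale all-zero {what} catalog")
    scale = mean / total
    out = {}
    for k, p in catalog.items():
        q = p * scale
        if q > 1.0:
            logger.warning("%s probability for %r capped at 1 after rescaling",
                           what, k)
            q = 1.0
        out[k] = q
    return out


@dataclass(frozen=True)
class TruthEntry:
    signal: InjectedSignal
    expected_prr: float


@dataclass(frozen=True)
class TruthLedger:
    """Ground truth of a generated set: the injected triples and, for each,
    the exact expected PRR under the configured probabilities."""

    entries: tuple[TruthEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug": e.signal.drug,
                    "pt": e.signal.pt,
                    "stratum": e.signal.stratum.value,
                    "multiplier": e.signal.multiplier,
                    "expected_prr": e.expected_prr,
                }
                for e in self.entries
            ],
            columns=["drug", "pt", "stratum", "multiplier", "expected_prr"],
        )


# ---------------------------------------------------------------------------
# Exact expected PRR under the generative model
# ---------------------------------------------------------------------------


def _active_injections(cfg: SynthConfig, pt: str,
                       stratum: AgeStratum) -> list[InjectedSignal]:
    folded = pt.strip().casefold()
    return [
        inj for inj in cfg.injected
        if inj.pt.casefold() == folded
        and (inj.stratum is AgeStratum.OVERALL or inj.stratum is stratum)
    ]


def _bern_prob(cfg: SynthConfig, pt: str, stratum: AgeStratum,
               fixed: Mapping[str, bool]) -> float:
    """Bernoulli-stage occurrence probability of ``pt`` in ``stratum``,
    marginal over injected drugs' exposures except those fixed."""
    q = cfg.pt_probs[_display_pt(cfg, pt)]
    injs = _active_injections(cfg, pt, stratum)
    fixed_mult = 1.0
    free: list[InjectedSignal] = []
    for inj in injs:
        if inj.drug in fixed:
            if fixed[inj.drug]:
                fixed_mult = max(fixed_mult, inj.multiplier)
        else:
            free.append(inj)
    probs = cfg.drug_probs
    total = 0.0
    for bits in itertools.product((False, True), repeat=len(free)):
        weight = 1.0
        mult = fixed_mult
        for inj, bit in zip(free, bits):
            p = probs[inj.drug]
            weight *= p if bit else (1.0 - p)
            if bit:
                mult = max(mult, inj.multiplier)
        total += weight * min(1.0, q * mult)
    return total


def _display_pt(cfg: SynthConfig, pt: str) -> str:
    folded = pt.strip().casefold()
    for name in cfg.pt_catalog:
        if name.casefold() == folded:
            return name
    raise ValidationError(f"PT {pt!r} not in catalog")


def _presence_prob(cfg: SynthConfig, pt: str, stratum: AgeStratum,
                   fixed: Mapping[str, bool]) -> float:
    """Final occurrence probability of ``pt`` including the empty-report
    fill-in (one catalog-weighted PT when the Bernoulli stage yields none).

    Cross-PT coupling through a drug injected on several PTs is treated as
    independent here; the computation is exact when each injected drug
    targets a single PT.
    """
    p_target = _bern_prob(cfg, pt, stratum, fixed)
    zero_all = 1.0 - p_target
    for other in cfg.pt_catalog:
        if other.casefold() == pt.strip().casefold():
            continue
        zero_all *= 1.0 - _bern_prob(cfg, other, stratum, fixed)
    weights = cfg.pt_catalog
    w = weights[_display_pt(cfg, pt)] / sum(weights.values())
    return p_target + zero_all * w


def expected_prr(cfg: SynthConfig, drug: str, pt: str,
                 stratum: AgeStratum = AgeStratum.OVERALL) -> float:
    """Exact expected PRR of (drug, pt) in ``stratum`` under the config.

    For OVERALL the exposed and background rates are age-distribution-
    weighted mixtures over the five buckets (the four bands plus unknown).
    """
    drug = str(drug).strip().casefold()
    if drug not in cfg.drug_catalog:
        raise ValidationError(f"drug {drug!r} not in catalog")
    if stratum is AgeStratum.OVERALL:
        weights = cfg.age_distribution
        strata = [s for s, w in weights.items() if w > 0]
    else:
        weights = {stratum: 1.0}
        strata = [stratum]
    rate_exposed = sum(
        weights[s] * _presence_prob(cfg, pt, s, {drug: True}) for s in strata
    )
    rate_background = sum(
        weights[s] * _presence_prob(cfg, pt, s, {drug: False}) for s in strata
    )
    total = sum(weights[s] for s in strata)
    return (rate_exposed / total) / (rate_background / total)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_reports(cfg: SynthConfig) -> tuple[ReportSet, TruthLedger]:
    """Draw a synthetic female report set and its truth ledger.

    Identical configs (including seed) produce identical report sets; every
    report is female with an age inside its band (or missing) and at least
    one drug and one PT.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports

    drug_names = list(cfg.drug_probs)
    drug_p = np.array([cfg.drug_probs[d] for d in drug_names])
    pt_names = list(cfg.pt_probs)
    pt_p = np.array([cfg.pt_probs[p] for p in pt_names])
    pt_index = {p.casefold(): j for j, p in enumerate(pt_names)}
    drug_index = {d: j for j, d in enumerate(drug_names)}

    # Drug exposures, with one weighted fill-in for drug-less reports.
    exposed = rng.random((n, len(drug_names))) < drug_p
    empty = ~exposed.any(axis=1)
    if empty.any():
        fill = rng.choice(len(drug_names), size=int(empty.sum()),
                          p=drug_p / drug_p.sum())
        exposed[np.nonzero(empty)[0], fill] = True

    # Age strata and integer ages.
    buckets = (*AGE_STRATA, AgeStratum.UNKNOWN)
    bucket_p = np.array([cfg.age_distribution[s] for s in buckets])
    codes = rng.choice(len(buckets), size=n, p=bucket_p / bucket_p.sum())
    ages = np.full(n, np.nan)
    for code, stratum in enumerate(buckets[:-1]):
        mask = codes == code
        if mask.any():
            lo, hi = _AGE_RANGES[stratum]
            ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    # PT occurrence probabilities, with injected multipliers applied.
    mult = np.ones((n, len(pt_names)))
    capped: list[InjectedSignal] = []
    for inj in cfg.injected:
        j = pt_index[inj.pt.casefold()]
        rows = exposed[:, drug_index[inj.drug]].copy()
        if inj.stratum is not AgeStratum.OVERALL:
            code = buckets.index(inj.stratum)
            rows &= codes == code
        mult[rows, j] = np.maximum(mult[rows, j], inj.multiplier)
        if pt_p[j] * inj.multiplier > 1.0:
            capped.append(inj)
    if capped:
        logger.warning(
            "injected probability capped at 1 for: %s",
            "; ".join(f"({i.drug}, {i.pt}, {i.stratum.value})" for i in capped),
        )
    probs = np.minimum(1.0, pt_p * mult)
    occurred = rng.random((n, len(pt_names))) < probs
    empty_pt = ~occurred.any(axis=1)
    if empty_pt.any():
        fill = rng.choice(len(pt_names), size=int(empty_pt.sum()),
                          p=pt_p / pt_p.sum())
        occurred[np.nonzero(empty_pt)[0], fill] = True

    width = max(7, len(str(n)))
    reports = []
    for i in range(n):
        reports.append(
            AEReport(
                report_id=f"R{i:0{width}d}",
                sex=Sex.FEMALE,
                age_years=None if math.isnan(ages[i]) else float(ages[i]),
                drugs=frozenset(
                    drug_names[j] for j in np.nonzero(exposed[i])[0]
                ),
                pts=frozenset(
                    pt_names[j] for j in np.nonzero(occurred[i])[0]
                ),
            )
        )
    rs = ReportSet(
        reports,
        provenance=(
            f"synthetic: n={n}, seed={cfg.seed}, "
            f"{len(drug_names)} drugs, {len(pt_names)} PTs, "
            f"{len(cfg.injected)} injected signal(s)"
        ),
    )
    ledger = TruthLedger(
        tuple(
            TruthEntry(inj, expected_prr(cfg, inj.drug, inj.pt, inj.stratum))
            for inj in cfg.injected
        )
    )
    return rs, ledger


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """Scorecard of a screen against the simulator's ground truth.

    ``sensitivity`` is the fraction of injected triples flagged (``None``
    under a null config with no injections); ``false_positive_rate`` is the
    flagged fraction of analyses not involving any injected PT (analyses of
    injected PTs are excluded from the denominator because a strong planted
    signal legitimately propagates to pooled entities and to the overall
    stratum); ``prr_errors`` maps each injected triple to estimated minus
    expected PRR.
    """

    sensitivity: float | None
    false_positive_rate: float
    prr_errors: dict[tuple[str, str, AgeStratum], float]


def recovery_report(
    results: Sequence[SignalResult], truth: TruthLedger
) -> RecoveryReport:
    """Score screen results against the truth ledger.

    Each injected triple must appear in the results as (drug-as-entity, pt,
    stratum); a missing triple means the results and ledger do not belong to
    the same run and raises.
    """
    index: dict[tuple[str, str, AgeStratum], SignalResult] = {}
    for res in results:
        index[(res.entity.casefold(), res.pt.casefold(), res.stratum)] = res

    injected_pts = {e.signal.pt.casefold() for e in truth.entries}
    recovered = 0
    prr_errors: dict[tuple[str, str, AgeStratum], float] = {}
    for entry in truth.entries:
        key = (entry.signal.drug, entry.signal.pt.casefold(), entry.signal.stratum)
        res = index.get(key)
        if res is None:
            raise ValidationError(
                f"injected triple {key!r} absent from screen results"
            )
        if res.is_signal:
            recovered += 1
        prr_errors[(entry.signal.drug, entry.signal.pt, entry.signal.stratum)] = (
            res.prr - entry.expected_prr
        )

    clean = [r for r in results if r.pt.casefold() not in injected_pts]
    false_pos = sum(1 for r in clean if r.is_signal)
    fpr = false_pos / len(clean) if clean else 0.0
    sensitivity = (
        recovered / len(truth.entries) if truth.entries else None
    )
    return RecoveryReport(sensitivity, fpr, prr_errors)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Background (non-statin) drugs with exposure probabilities chosen so that
#: drug-less reports are uncommon and the fill-in stays a small correction.
_BACKGROUND_DRUGS: dict[str, float] = {
    "aspirin": 0.30,
    "paracetamol": 0.25,
    "metformin": 0.20,
    "lisinopril": 0.18,
    "omeprazole": 0.15,
    "ibuprofen": 0.15,
    "levothyroxine": 0.12,
    "amlodipine": 0.12,
}

#: Common background PTs keeping event-less reports rare.
_BACKGROUND_PTS: dict[str, float] = {
    "Drug ineffective": 0.50,
    "Nausea": 0.30,
    "Headache": 0.25,
    "Fatigue": 0.20,
    "Dizziness": 0.18,
    "Diarrhoea": 0.15,
    "Rash": 0.12,
    "Vomiting": 0.10,
}

#: Ovary/uterus PTs (all inside the bundled vocabulary) with rare baselines.
_OVARY_UTERUS_PTS: dict[str, float] = {
    "Ovarian cyst": 0.004,
    "Ovarian adenoma": 0.0008,
    "Uterine polyp": 0.003,
    "Uterine leiomyoma": 0.005,
    "Endometrial cancer": 0.002,
    "Adenocarcinoma of the cervix": 0.0006,
    "Cervical polyp": 0.001,
    "Endometrial hyperplasia": 0.0015,
    "Endometrial disorder": 0.001,
    "Adenomyosis": 0.0012,
    "Endometriosis": 0.006,
    "Uterine prolapse": 0.002,
    "Endometrial hypertrophy": 0.0008,
    "Cervical dysplasia": 0.0015,
    "Androgenetic alopecia": 0.001,
    "Polycystic ovaries": 0.003,
    "Blood testosterone increased": 0.0008,
    "Dysfunctional uterine bleeding": 0.0015,
    "Uterine haemorrhage": 0.002,
    "Menorrhagia": 0.005,
    "Menstruation irregular": 0.004,
    "Amenorrhoea": 0.003,
    "Menopausal symptoms": 0.003,
    "Postmenopausal haemorrhage": 0.002,
    "Dyspareunia": 0.0015,
    "Sexual dysfunction": 0.002,
    "Libido decreased": 0.003,
}

#: Statin exposure probabilities proportional to the relative report volumes
#: of the seven statins in a large female extract, totalling ~20% class
#: exposure before the fill-in correction.
_STATIN_EXPOSURE: dict[str, float] = {
    "atorvastatin": 0.0823,
    "simvastatin": 0.0572,
    "rosuvastatin": 0.0372,
    "pravastatin": 0.0139,
    "lovastatin": 0.0064,
    "fluvastatin": 0.0020,
    "pitavastatin": 0.0012,
}

#: Age mix of a large female statin extract: heavy 40-59 and 60+ bands and
#: roughly 29% of reports with no usable age.
_PAPERLIKE_AGE_MIX: dict[AgeStratum, float] = {
    AgeStratum.S_0_18: 0.002,
    AgeStratum.S_19_39: 0.018,
    AgeStratum.S_40_59: 0.20,
    AgeStratum.S_60_PLUS: 0.49,
    AgeStratum.UNKNOWN: 0.29,
}


def paperlike(
    n_reports: int = 20_000,
    seed: int = 0,
    injected: Iterable[InjectedSignal] = (),
) -> SynthConfig:
    """Preset emulating the shape of a female statin extract: ~20% of reports
    exposed to a statin-class member, an age mix of roughly (0.2%, 1.8%, 20%,
    49%) across the four bands with ~29% missing ages, rare ovary/uterus PT
    baselines and common background events."""
    return SynthConfig(
        n_reports=n_reports,
        drug_catalog={**_STATIN_EXPOSURE, **_BACKGROUND_DRUGS},
        pt_catalog={**_OVARY_UTERUS_PTS, **_BACKGROUND_PTS},
        age_distribution=_PAPERLIKE_AGE_MIX,
        injected=tuple(injected),
        seed=seed,
    )


def injection_benchmark(
    n_reports: int = 50_000,
    seed: int = 0,
    drug: str = "simvastatin",
    pt: str = "Ovarian adenoma",
    exposure: float = 0.1,
    baseline: float = 0.002,
    multiplier: float = 10.0,
    stratum: AgeStratum = AgeStratum.OVERALL,
) -> SynthConfig:
    """Single-signal benchmark config: one drug at the given exposure, one
    rare PT at the given baseline, one injected multiplier, against common
    background drugs and events."""
    drug = str(drug).strip().casefold()
    drug_catalog = {drug: exposure}
    for name, p in _BACKGROUND_DRUGS.items():
        drug_catalog.setdefault(name, p)
    pt_catalog = {pt: baseline}
    for name, p in ("Menorrhagia", 0.005), ("Endometriosis", 0.006), \
            ("Uterine polyp", 0.003), ("Amenorrhoea", 0.003), \
            ("Ovarian cyst", 0.004):
        if name.casefold() != pt.casefold():
            pt_catalog[name] = p
    pt_catalog.update(_BACKGROUND_PTS)
    return SynthConfig(
        n_reports=n_reports,
        drug_catalog=drug_catalog,
        pt_catalog=pt_catalog,
        age_distribution=_PAPERLIKE_AGE_MIX,
        injected=(InjectedSignal(drug, pt, stratum, multiplier),),
        seed=seed,
    )


def synthetic_cohort(
    drug: str,
    stratum_counts: Mapping[AgeStratum, int],
    prefix: str = "C",
) -> ReportSet:
    """Deterministic all-female cohort with exact per-stratum report counts,
    every report exposed to ``drug``; handy for demography arithmetic on
    published marginal counts."""
    reports = []
    i = 0
    for stratum, count in stratum_counts.items():
        age = _REPRESENTATIVE_AGE[stratum]
        for _ in range(int(count)):
            reports.append(
                AEReport(
                    report_id=f"{prefix}{i:08d}",
                    sex=Sex.FEMALE,
                    age_years=age,
                    drugs=frozenset({str(drug).strip().casefold()}),
                    pts=frozenset(),
                )
            )
            i += 1
    return ReportSet(reports, provenance=f"deterministic cohort for {drug!r}")


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def config_to_dict(cfg: SynthConfig) -> dict:
    return {
        "n_reports": cfg.n_reports,
        "seed": cfg.seed,
        "drug_catalog": dict(cfg.drug_catalog),
        "pt_catalog": dict(cfg.pt_catalog),
        "age_distribution": {s.value: p for s, p in cfg.age_distribution.items()},
        "drugs_per_report_mean": cfg.drugs_per_report_mean,
        "pts_per_report_mean": cfg.pts_per_report_mean,
        "injected": [
            {
                "drug": inj.drug,
                "pt": inj.pt,
                "stratum": inj.stratum.value,
                "multiplier": inj.multiplier,
            }
            for inj in cfg.injected
        ],
    }


def config_from_dict(data: Mapping) -> SynthConfig:
    stratum_by_value = {s.value: s for s in AgeStratum}
    ages = {
        stratum_by_value[str(k)]: float(v)
        for k, v in dict(data["age_distribution"]).items()
    }
    injected = tuple(
        InjectedSignal(
            drug=item["drug"],
            pt=item["pt"],
            stratum=stratum_by_value[str(item.get("stratum", "overall"))],
            multiplier=float(item.get("multiplier", 2.0)),
        )
        for item in data.get("injected", ())
    )
    return SynthConfig(
        n_reports=int(data["n_reports"]),
        drug_catalog=dict(data["drug_catalog"]),
        pt_catalog=dict(data["pt_catalog"]),
        age_distribution=ages,
        injected=injected,
        seed=int(data.get("seed", 0)),
        drugs_per_report_mean=data.get("drugs_per_report_mean"),
        pts_per_report_mean=data.get("pts_per_report_mean"),
    )


def with_seed(cfg: SynthConfig, seed: int) -> SynthConfig:
    """Copy of a config with a different seed."""
    return replace(cfg, seed=int(seed))
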