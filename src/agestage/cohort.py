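"""Individual life-history cohorts: reading, validation and trait summaries.

A cohort is the raw material of an age-stage, two-sex life table: one record
per individual, following it from the day its egg was laid (age 0) through
the immature stages (egg, larva, pupa) to the adult stage (female or male)
and death, with the stage occupied and the number of eggs laid recorded for
every day of life.  Individuals that die before adulthood stay in the cohort
denominator with sex ``undetermined`` -- both sexes and all pre-adult deaths
count in the life table.

The on-disk format is a long CSV with one row per individual per day alive::

    individual_id,age,stage,eggs_laid
    F1,0,egg,0
    F1,1,larva,0
    ...

Ages are 0-based calendar days; ``age 0`` is the day the egg was laid and an
individual "alive at age x" was observed on day x.  ``death_age`` is the last
observed day, so lifespan = death_age + 1 days.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

STAGES = ("egg", "larva", "pupa", "female", "male")
PREADULT_STAGES = ("egg", "larva", "pupa")
ADULT_STAGES = ("female", "male")
STAGE_CODE = {s: i for i, s in enumerate(STAGES)}

# development order; the two adult stages share a rank (an individual has one
# adult stage only, never both)
_STAGE_RANK = {"egg": 0, "larva": 1, "pupa": 2, "female": 3, "male": 3}

REQUIRED_COLUMNS = ("individual_id", "age", "stage", "eggs_laid")

#: names of the traits reported by :func:`summarize_traits`, in output order
TRAIT_NAMES = (
    "egg",
    "larva",
    "pupa",
    "preadult",
    "female_longevity",
    "male_longevity",
    "apop",
    "tpop",
    "oviposition_days",
    "fecundity",
)

TPOP_CONVENTION = (
    "TPOP = age of first oviposition + 1 (days since the egg was laid, "
    "counting the laying day), so TPOP = pre-adult duration + APOP exactly"
)


class LifeHistoryFormatError(ValueError):
    """The life-history file does not have the expected columns/layout."""


class CohortValidationError(ValueError):
    """Daily records violate the life-history invariants."""


@dataclass(frozen=True)
class IndividualRecord:
    """One insect's complete daily life history.

    Parameters
    ----------
    individual_id
        Free-text token identifying the individual.
    stages
        Stage occupied on each day of life, index = age (0-based).  The
        sequence must be non-decreasing in the development order
        egg < larva < pupa < adult.
    eggs
        Eggs laid on each day of life; nonzero only on female-adult days.
    """

    individual_id: str
    stages: tuple[str, ...]
    eggs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError(f"{self.individual_id}: empty life history")
        if len(self.stages) != len(self.eggs):
            raise ValueError(
                f"{self.individual_id}: stages and eggs must have equal length"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def death_age(self) -> int:
        """Last age (day) the individual was observed alive."""
        return len(self.stages) - 1

    @property
    def lifespan(self) -> int:
        """Days alive (death_age + 1)."""
        return len(self.stages)

    @cached_property
    def sex(self) -> str:
        if "female" in self.stages:
            return "female"
        if "male" in self.stages:
            return "male"
        return "undetermined"

    @property
    def died_pre_adult(self) -> bool:
        return self.sex == "undetermined"

    @cached_property
    def stage_durations(self) -> dict[str, int]:
        """Days spent in each stage actually entered."""
        return dict(Counter(self.stages))

    def completed(self, stage: str) -> bool:
        """True if the individual left `stage` for a later one (did not die
        mid-stage).  Always False for stages never entered."""
        if stage not in self.stage_durations:
            return False
        rank = _STAGE_RANK[stage]
        return any(_STAGE_RANK[s] > rank for s in self.stage_durations)

    @cached_property
    def emergence_age(self) -> Optional[int]:
        """Age of the first adult day, i.e. the pre-adult duration; None for
        individuals that died before adulthood."""
        for x, s in enumerate(self.stages):
            if s in ADULT_STAGES:
                return x
        return None

    # -- reproduction ---------------------------------------------------
    @property
    def total_eggs(self) -> int:
        return int(sum(self.eggs))

    @cached_property
    def first_oviposition_age(self) -> Optional[int]:
        for x, e in enumerate(self.eggs):
            if e > 0:
                return x
        return None

    @property
    def oviposition_days(self) -> int:
        return int(sum(1 for e in self.eggs if e > 0))

    @property
    def apop(self) -> Optional[int]:
        """Adult pre-oviposition period: first oviposition age minus
        emergence age; None if the female never laid."""
        if self.first_oviposition_age is None or self.emergence_age is None:
            return None
        return self.first_oviposition_age - self.emergence_age

    @property
    def tpop(self) -> Optional[int]:
        """Total pre-oviposition period in days since the egg was laid,
        counting the laying day (first oviposition age + 1)."""
        if self.first_oviposition_age is None:
            return None
        return self.first_oviposition_age + 1


@dataclass(frozen=True)
class Cohort:
    """A set of individual life histories reared together (one treatment)."""

    individuals: tuple[IndividualRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.individuals) == 0:
            raise CohortValidationError("empty cohort")

    @property
    def n(self) -> int:
        """Initial cohort size (number of eggs started)."""
        return len(self.individuals)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def x_max(self) -> int:
        return max(ind.death_age for ind in self.individuals)

    @property
    def females(self) -> tuple[IndividualRecord, ...]:
        return tuple(i for i in self.individuals if i.sex == "female")

    @property
    def males(self) -> tuple[IndividualRecord, ...]:
        return tuple(i for i in self.individuals if i.sex == "male")

    def to_frame(self) -> pd.DataFrame:
        """Long daily-observation table (one row per individual per day)."""
        rows = {c: [] for c in REQUIRED_COLUMNS}
        for ind in self.individuals:
            k = ind.lifespan
            rows["individual_id"].extend([ind.individual_id] * k)
            rows["age"].extend(range(k))
            rows["stage"].extend(ind.stages)
            rows["eggs_laid"].extend(ind.eggs)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "") -> "Cohort":
        """Build a cohort from a long daily table (assumed already valid)."""
        inds = []
        for ident, grp in df.groupby("individual_id", sort=True):
            grp = grp.sort_values("age")
            inds.append(
                IndividualRecord(
                    individual_id=str(ident),
                    stages=tuple(grp["stage"]),
                    eggs=tuple(int(e) for e in grp["eggs_laid"]),
                )
            )
        return cls(individuals=tuple(inds), label=label)

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Bootstrap resample of n individuals with replacement.

        Individual ids are suffixed with the draw index so the resampled
        cohort still has unique ids.
        """
        idx = rng.integers(0, self.n, size=self.n)
        inds = tuple(
            IndividualRecord(
                individual_id=f"{self.individuals[i].individual_id}~{k}",
                stages=self.individuals[i].stages,
                eggs=self.individuals[i].eggs,
            )
            for k, i in enumerate(idx)
        )
        return Cohort(individuals=inds, label=self.label)


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """List of invariant violations found in a cohort (empty = valid)."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.ok:
            return "cohort valid: no violations"
        return "\n".join(self.violations)


def validate_frame(df: pd.DataFrame) -> ValidationReport:
    """Check the daily-observation invariants on a long table.

    Checks, per individual: contiguous 0-based ages with no gaps or
    duplicates, known stage names, non-decreasing stage order, a single adult
    stage, non-negative egg counts, and eggs only on female days.
    """
    report = ValidationReport()
    for ident, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("age")
        ages = grp["age"].to_numpy()
        if len(np.unique(ages)) != len(ages):
            report.violations.append(f"{ident}: duplicate age rows")
        expected = np.arange(len(ages))
        if not np.array_equal(np.sort(ages), expected):
            report.violations.append(
                f"{ident}: age gap (ages must cover 0..death_age contiguously)"
            )
        stages = list(grp["stage"])
        bad = sorted({s for s in stages if s not in STAGES})
        if bad:
            report.violations.append(f"{ident}: unknown stage name(s) {bad}")
            continue
        ranks = [_STAGE_RANK[s] for s in stages]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            report.violations.append(f"{ident}: stage regression (development order violated)")
        if "female" in stages and "male" in stages:
            report.violations.append(f"{ident}: both adult stages present")
        eggs = grp["eggs_laid"].to_numpy()
        if (eggs < 0).any():
            report.violations.append(f"{ident}: negative eggs_laid")
        nonfemale = np.array([s != "female" for s in stages])
        if (eggs[nonfemale] > 0).any():
            report.violations.append(f"{ident}: eggs_laid > 0 on a non-female day")
    return report


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Validate an in-memory cohort; reports violations, never raises."""
    report = validate_frame(cohort.to_frame())
    for ind in cohort.individuals:
        adult = any(s in ADULT_STAGES for s in ind.stages)
        if ind.sex == "undetermined" and adult:
            report.violations.append(f"{ind.individual_id}: adult with undetermined sex")
        if not adult and ind.total_eggs > 0:
            report.violations.append(f"{ind.individual_id}: pre-adult individual laid eggs")
    return report


# ---------------------------------------------------------------------------
# I/O


def read_life_history(path: str | Path, label: Optional[str] = None) -> Cohort:
    """Read and validate a daily life-history CSV.

    Raises
    ------
    LifeHistoryFormatError
        Missing columns or non-numeric age/egg fields.
    CohortValidationError
        Empty data section, age gaps, stage regressions, negative eggs, ...
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError("empty cohort") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LifeHistoryFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}"
        )
    if len(df) == 0:
        raise CohortValidationError("empty cohort")
    df["individual_id"] = df["individual_id"].astype(str)
    for col in ("age", "eggs_laid"):
        try:
            df[col] = df[col].astype(int)
        except (ValueError, TypeError) as exc:
            raise LifeHistoryFormatError(f"{path}: column {col!r} must be integer") from exc
    df["stage"] = df["stage"].astype(str).str.strip().str.lower()
    report = validate_frame(df)
    if not report.ok:
        raise CohortValidationError(str(report))
    return Cohort.from_frame(df, label=label if label is not None else path.stem)


def write_life_history(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the daily CSV format (round-trip safe)."""
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trait summaries


@dataclass(frozen=True)
class TraitStat:
    mean: float
    se: float
    n: int


@dataclass
class TraitSummary:
    """Per-trait mean, SE and contributing n (the Table-1 style summary).

    Durations are reported over individuals that completed the stage; APOP,
    TPOP and oviposition days over females that actually oviposited;
    fecundity over all adult females.  Undefined traits carry ``n = 0`` and
    NaN mean.
    """

    traits: dict[str, TraitStat]
    convention: str = TPOP_CONVENTION

    def __getitem__(self, name: str) -> TraitStat:
        return self.traits[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": list(self.traits),
                "mean": [t.mean for t in self.traits.values()],
                "se": [t.se for t in self.traits.values()],
                "n": [t.n for t in self.traits.values()],
            }
        )


def _stat(values: Sequence[float]) -> TraitStat:
    n = len(values)
    if n == 0:
        return TraitStat(mean=float("nan"), se=float("nan"), n=0)
    arr = np.asarray(values, dtype=float)
    se = float(np.std(arr, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return TraitStat(mean=float(arr.mean()), se=se, n=n)


def individual_trait(ind: IndividualRecord, trait: str) -> Optional[float]:
    """The per-individual value behind each summary trait; None if the
    individual does not contribute to that trait."""
    if trait in PREADULT_STAGES:
        return float(ind.stage_durations[trait]) if ind.completed(trait) else None
    if trait == "preadult":
        return float(ind.emergence_age) if ind.emergence_age is not None else None
    if trait == "female_longevity":
        return float(ind.stage_durations["female"]) if ind.sex == "female" else None
    if trait == "male_longevity":
        return float(ind.stage_durations["male"]) if ind.sex == "male" else None
    if trait == "apop":
        return float(ind.apop) if ind.apop is not None else None
    if trait == "tpop":
        return float(ind.tpop) if ind.tpop is not None else None
    if trait == "oviposition_days":
        if ind.sex == "female" and ind.total_eggs > 0:
            return float(ind.oviposition_days)
        return None
    if trait == "fecundity":
        return float(ind.total_eggs) if ind.sex == "female" else None
    raise KeyError(f"unknown trait {trait!r}")


def summarize_traits(cohort: Cohort) -> TraitSummary:
    """Compute mean +/- SE for development times, longevity, APOP, TPOP,
    oviposition days and fecundity.  SE is the sample SE (sd/sqrt(n),
    ddof=1); NaN when fewer than two individuals contribute."""
    traits: dict[str, TraitStat] = {}
    for name in TRAIT_NAMES:
        values = [
            v
            for ind in cohort.individuals
            if (v := individual_trait(ind, name)) is not None
        ]
        traits[name] = _stat(values)
    return TraitSummary(traits=traits)
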