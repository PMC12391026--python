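"""Germination-trial domain types, table I/O and the species inclusion filter.

A germination trial exposes seeds of one species to three day-length
treatments — short day (6 h light / 18 h dark), equal day (12 h / 12 h) and
long day (18 h / 6 h) — and records how many seeds germinate out of how many
were sown.  The equal-day treatment is the reference level for all downstream
treatment contrasts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Treatment",
    "GerminationRecord",
    "SpeciesTraits",
    "FilterDecision",
    "FilterReason",
    "GerminationTableError",
    "parse_treatment",
    "read_germination_table",
    "write_germination_table",
    "read_traits_table",
    "apply_inclusion_filter",
    "group_by_species",
]


class Treatment(enum.Enum):
    """One of the three photoperiod treatments.

    EQUAL (12 h light / 12 h dark) is the reference level: the fitted
    treatment contrasts are LONG − EQUAL and SHORT − EQUAL on the log-odds
    scale.
    """

    SHORT = "6L/18D"
    EQUAL = "12L/12D"
    LONG = "18L/6D"


#: Accepted spellings per treatment (lower-cased, whitespace removed).
_TREATMENT_DIALECTS: Mapping[str, Treatment] = {
    "6l/18d": Treatment.SHORT,
    "short": Treatment.SHORT,
    "short-day": Treatment.SHORT,
    "short_day": Treatment.SHORT,
    "12l/12d": Treatment.EQUAL,
    "equal": Treatment.EQUAL,
    "equal-day": Treatment.EQUAL,
    "equal_day": Treatment.EQUAL,
    "18l/6d": Treatment.LONG,
    "long": Treatment.LONG,
    "long-day": Treatment.LONG,
    "long_day": Treatment.LONG,
}


class GerminationTableError(ValueError):
    """Raised when a germination table fails validation; lists row numbers."""


def parse_treatment(code_text: str, row: int | None = None) -> Treatment:
    """Parse a treatment code such as ``"6L/18D"``, ``"short"`` or ``"LONG"``.

    Case-insensitive and whitespace-tolerant.  Anything outside the three
    recognised treatments raises rather than guessing.
    """
    if not isinstance(code_text, str) or not code_text.strip():
        where = f" (row {row})" if row is not None else ""
        raise GerminationTableError(f"empty treatment code{where}")
    key = "".join(code_text.split()).lower()
    try:
        return _TREATMENT_DIALECTS[key]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise GerminationTableError(
            f"unknown treatment code {code_text!r}{where}; expected one of "
            "6L/18D, 12L/12D, 18L/6D or short/equal/long"
        ) from None


@dataclass(frozen=True)
class GerminationRecord:
    """Binomial germination outcome for one species under one treatment."""

    species: str
    treatment: Treatment
    n_sown: int
    n_germinated: int
    source_rows: tuple[int, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.n_sown < 0 or self.n_germinated < 0:
            raise GerminationTableError(
                f"negative count for {self.species} / {self.treatment.value}"
            )
        if self.n_germinated > self.n_sown:
            raise GerminationTableError(
                f"{self.species} / {self.treatment.value}: germinated "
                f"({self.n_germinated}) exceeds sown ({self.n_sown})"
            )

    @property
    def fraction(self) -> float:
        return self.n_germinated / self.n_sown if self.n_sown else 0.0


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species trait and environment covariates.

    Latitude is stored signed (southern latitudes negative); models consume
    its absolute value.  Missing values are ``None``.
    """

    species: str
    seed_mass_mg: float | None = None
    growth_form: str | None = None
    latitude_deg: float | None = None
    lai: float | None = None
    alpine: bool | None = None

    def __post_init__(self) -> None:
        if self.seed_mass_mg is not None and self.seed_mass_mg <= 0:
            raise ValueError(f"{self.species}: seed mass must be positive")
        if self.lai is not None and self.lai < 0:
            raise ValueError(f"{self.species}: LAI must be non-negative")


class FilterReason(enum.Enum):
    OK = "ok"
    LOW_PERCENT_ALL_TREATMENTS = "low_percent_all_treatments"
    FEWER_THAN_FIVE_GERMINANTS = "fewer_than_five_germinants"


@dataclass(frozen=True)
class FilterDecision:
    species: str
    retained: bool
    reason: FilterReason

    def __post_init__(self) -> None:
        if self.retained != (self.reason is FilterReason.OK):
            raise ValueError("retained must be True exactly when reason is ok")


_GERM_COLUMNS = ["species", "treatment", "n_sown", "n_germinated"]


def read_germination_table(path: str | Path) -> list[GerminationRecord]:
    """Read and validate a germination CSV.

    Expects columns ``species,treatment,n_sown,n_germinated``.  Duplicate
    species × treatment rows are aggregated by summing counts.  All
    validation problems are collected and reported together with the 1-based
    data row numbers they occur on.
    """
    df = pd.read_csv(path, dtype={"species": str, "treatment": str})
    missing = [c for c in _GERM_COLUMNS if c not in df.columns]
    if missing:
        raise GerminationTableError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )

    problems: list[str] = []
    parsed: dict[tuple[str, Treatment], list[tuple[int, int, int]]] = {}
    order: list[tuple[str, Treatment]] = []
    for i, row in df.iterrows():
        rownum = int(i) + 1
        try:
            treatment = parse_treatment(row["treatment"], row=rownum)
        except GerminationTableError as exc:
            problems.append(str(exc))
            continue
        try:
            sown = _as_count(row["n_sown"])
            germ = _as_count(row["n_germinated"])
        except ValueError as exc:
            problems.append(f"row {rownum}: {exc}")
            continue
        if germ > sown:
            problems.append(
                f"row {rownum}: n_germinated ({germ}) exceeds n_sown ({sown})"
            )
            continue
        key = (str(row["species"]), treatment)
        if key not in parsed:
            parsed[key] = []
            order.append(key)
        parsed[key].append((rownum, sown, germ))

    if problems:
        raise GerminationTableError(
            f"{path}: invalid germination table:\n  " + "\n  ".join(problems)
        )

    return [
        GerminationRecord(
            species=species,
            treatment=treatment,
            n_sown=sum(s for _, s, _ in rows),
            n_germinated=sum(g for _, _, g in rows),
            source_rows=tuple(r for r, _, _ in rows),
        )
        for (species, treatment), rows in ((k, parsed[k]) for k in order)
    ]


def _as_count(value: object) -> int:
    f = float(value)  # type: ignore[arg-type]
    if not f.is_integer():
        raise ValueError(f"count {value!r} is not an integer")
    n = int(f)
    if n < 0:
        raise ValueError(f"count {value!r} is negative")
    return n


def write_germination_table(records: Iterable[GerminationRecord], path: str | Path) -> None:
    """Write records back to the CSV dialect :func:`read_germination_table` reads."""
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "treatment": r.treatment.value,
                "n_sown": r.n_sown,
                "n_germinated": r.n_germinated,
            }
            for r in records
        ],
        columns=_GERM_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_traits_table(path: str | Path) -> list[SpeciesTraits]:
    """Read a species trait CSV (empty cells become ``None``)."""
    df = pd.read_csv(path, dtype={"species": str, "growth_form": str})
    required = ["species"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GerminationTableError(f"{path}: missing column(s) {missing}")

    def _opt(row: pd.Series, col: str, cast) -> object | None:
        if col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesTraits(
                species=str(row["species"]),
                seed_mass_mg=_opt(row, "seed_mass_mg", float),
                growth_form=_opt(row, "growth_form", str),
                latitude_deg=_opt(row, "latitude_deg", float),
                lai=_opt(row, "lai", float),
                alpine=_opt(row, "alpine", lambda v: bool(int(v))),
            )
        )
    return out


def group_by_species(
    records: Iterable[GerminationRecord],
) -> dict[str, list[GerminationRecord]]:
    """Group records by species, preserving first-appearance order."""
    grouped: dict[str, list[GerminationRecord]] = {}
    for record in records:
        grouped.setdefault(record.species, []).append(record)
    return grouped


def aggregate_by_treatment(
    records: Sequence[GerminationRecord],
) -> dict[Treatment, GerminationRecord]:
    """Collapse one species' records to one summed record per treatment."""
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    (name,) = species
    out: dict[Treatment, GerminationRecord] = {}
    for treatment in Treatment:
        subset = [r for r in records if r.treatment is treatment]
        if not subset:
            continue
        out[treatment] = GerminationRecord(
            species=name,
            treatment=treatment,
            n_sown=sum(r.n_sown for r in subset),
            n_germinated=sum(r.n_germinated for r in subset),
            source_rows=tuple(n for r in subset for n in r.source_rows),
        )
    return out


def apply_inclusion_filter(records: Sequence[GerminationRecord]) -> FilterDecision:
    """Decide whether one species has enough germination to be analysed.

    A species is excluded when its per-treatment germination fraction is
    strictly below 5% in every treatment, or when strictly fewer than five
    seeds germinated across the three treatments combined.  Both
    inequalities are strict, so exact ties (5% in a treatment, exactly five
    germinants) retain the species.  When both rules fire, the low-percent
    reason is reported.
    """
    by_treatment = aggregate_by_treatment(records)
    missing = [t for t in Treatment if t not in by_treatment]
    if missing:
        species = records[0].species if records else "<empty>"
        raise GerminationTableError(
            f"{species}: missing treatment level(s) "
            + ", ".join(t.value for t in missing)
        )
    (name,) = {r.species for r in records}
    all_low_percent = all(r.fraction < 0.05 for r in by_treatment.values())
    total_germinated = sum(r.n_germinated for r in by_treatment.values())
    if all_low_percent:
        return FilterDecision(name, False, FilterReason.LOW_PERCENT_ALL_TREATMENTS)
    if total_germinated < 5:
        return FilterDecision(name, False, FilterReason.FEWER_THAN_FIVE_GERMINANTS)
    return FilterDecision(name, True, FilterReason.OK)
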