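"""Read, validate, aggregate and write species trait tables.

A trait table holds one row per species (or per population before
aggregation) with per-sex mean body size (snout--vent length, mm) and mean
adult age (years), plus optional sample sizes and standard errors.  Sizes
are required and must be strictly positive so that log transforms are
defined; ages are optional so that size-only analyses remain runnable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from ._errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default mapping from SpeciesRecord field -> column header in the file.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "species": "species",
    "female_size": "female_size",
    "male_size": "male_size",
    "female_age": "female_age",
    "male_age": "male_age",
    "female_n": "female_n",
    "male_n": "male_n",
    "female_size_se": "female_size_se",
    "male_size_se": "male_size_se",
    "population": "population",
}

_REQUIRED_FIELDS = ("species", "female_size", "male_size")
_OPTIONAL_FLOAT_FIELDS = ("female_age", "male_age", "female_size_se", "male_size_se")
_OPTIONAL_INT_FIELDS = ("female_n", "male_n")


@dataclass(frozen=True)
class SpeciesRecord:
    """Per-sex mean size and age for one species (or one population of it).

    Attributes
    ----------
    species : str
        Species name; must be nonempty and unique within an aggregated table.
    female_size, male_size : float
        Mean snout--vent length in mm, strictly positive.
    female_age, male_age : float or None
        Mean adult age in years, strictly positive when present.  Records
        without ages are usable for size-dimorphism analyses only.
    female_n, male_n : int or None
        Sample sizes behind the means.
    female_size_se, male_size_se : float or None
        Standard errors of the size means.
    population : str or None
        Label distinguishing multiple populations of one species.
    """

    species: str
    female_size: float
    male_size: float
    female_age: float | None = None
    male_age: float | None = None
    female_n: int | None = None
    male_n: int | None = None
    female_size_se: float | None = None
    male_size_se: float | None = None
    population: str | None = None

    def __post_init__(self) -> None:
        if not str(self.species).strip():
            raise ValidationError("species name must be nonempty")
        for name in ("female_size", "male_size"):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{name} must be finite and > 0 for species "
                    f"{self.species!r}, got {value!r}"
                )
        for name in ("female_age", "male_age"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value <= 0):
                raise ValidationError(
                    f"{name} must be finite and > 0 for species "
                    f"{self.species!r}, got {value!r}"
                )
        for name in ("female_size_se", "male_size_se"):
            value = getattr(self, name)
            if value is not None and (not math.isfinite(value) or value < 0):
                raise ValidationError(
                    f"{name} must be >= 0 for species {self.species!r}, got {value!r}"
                )
        for name in ("female_n", "male_n"):
            value = getattr(self, name)
            if value is not None and (int(value) != value or value < 1):
                raise ValidationError(
                    f"{name} must be a positive integer for species "
                    f"{self.species!r}, got {value!r}"
                )

    @property
    def has_ages(self) -> bool:
        return self.female_age is not None and self.male_age is not None


@dataclass
class TraitTable:
    """Ordered, validated collection of :class:`SpeciesRecord`.

    Iteration order is the input order.  Before aggregation, several
    records may share a species name provided they carry distinct
    population labels; afterwards species names are unique.
    """

    records: list[SpeciesRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str | None]] = set()
        for rec in self.records:
            key = (rec.species, rec.population)
            if key in seen:
                raise ValidationError(
                    f"duplicate record for species {rec.species!r}"
                    + (f", population {rec.population!r}" if rec.population else "")
                )
            seen.add(key)

    def __iter__(self) -> Iterator[SpeciesRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return [rec.species for rec in self.records]

    def subset(self, names: Iterable[str]) -> "TraitTable":
        """Rows whose species name is in ``names``, preserving table order."""
        wanted = set(names)
        return TraitTable(
            records=[r for r in self.records if r.species in wanted],
            provenance=self.provenance,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in fields(SpeciesRecord)]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )


def _parse_cell(raw: object) -> tuple[float | None, float | None]:
    """Parse a numeric cell, splitting ``mean ± SE`` strings when present."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None, None
    if isinstance(raw, (int, float)):
        return float(raw), None
    text = str(raw).strip()
    if not text:
        return None, None
    for sep in ("±", "+/-"):
        if sep in text:
            mean_part, se_part = text.split(sep, 1)
            return float(mean_part.strip()), float(se_part.strip())
    return float(text), None


def read_trait_table(
    path: str | Path,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TraitTable:
    """Read a delimited species trait table.

    Parameters
    ----------
    path : path to a UTF-8 CSV/TSV file with a header row.
    delimiter : explicit field delimiter; sniffed from the file when None.
    column_map : mapping from record field names to the file's column
        headers, overriding :data:`DEFAULT_COLUMN_MAP` entries.

    Size and age cells may be plain numbers or ``mean ± SE`` strings; the
    SE part of a size cell populates the corresponding ``*_size_se`` field
    unless a dedicated SE column is present.

    Raises
    ------
    FormatError
        If a required column is missing or the file cannot be parsed.
    ValidationError
        If any row violates a record invariant; the message cites the
        offending data row numbers (1-based, excluding the header).
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=delimiter, engine="python", dtype=object)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    df.columns = [str(c).strip() for c in df.columns]
    for required in _REQUIRED_FIELDS:
        if colmap[required] not in df.columns:
            raise FormatError(
                f"required column {colmap[required]!r} missing from {path} "
                f"(found: {list(df.columns)})"
            )

    records: list[SpeciesRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowdict = dict(zip(df.columns, row))
        try:
            kwargs: dict[str, object] = {}
            species = rowdict.get(colmap["species"])
            kwargs["species"] = "" if species is None else str(species).strip()
            for fname in ("female_size", "male_size"):
                mean, se = _parse_cell(rowdict.get(colmap[fname]))
                kwargs[fname] = mean
                if se is not None:
                    kwargs[f"{fname}_se"] = se
            for fname in _OPTIONAL_FLOAT_FIELDS:
                if kwargs.get(fname) is not None:
                    continue  # SE already captured from a "mean ± SE" cell
                mean, _ = _parse_cell(rowdict.get(colmap[fname]))
                if mean is not None:
                    kwargs[fname] = mean
            for fname in _OPTIONAL_INT_FIELDS:
                mean, _ = _parse_cell(rowdict.get(colmap[fname]))
                if mean is not None:
                    kwargs[fname] = int(mean)
            pop = rowdict.get(colmap["population"])
            if pop is not None and not (isinstance(pop, float) and math.isnan(pop)):
                text = str(pop).strip()
                if text:
                    kwargs["population"] = text
            if kwargs["female_size"] is None or kwargs["male_size"] is None:
                raise ValidationError(
                    f"missing size value for species {kwargs['species']!r}"
                )
            records.append(SpeciesRecord(**kwargs))  # type: ignore[arg-type]
        except (ValidationError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{len(problems)} invalid row(s) in {path}:\n" + "\n".join(problems)
        )
    return TraitTable(records=records, provenance=str(path))


def write_trait_table(
    table: TraitTable, path: str | Path, delimiter: str = ","
) -> None:
    """Write a tidy delimited file that :func:`read_trait_table` round-trips."""
    df = table.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False, na_rep="")


def _weighted_mean(
    values: Sequence[float], weights: Sequence[float | None]
) -> float:
    if any(w is None for w in weights):
        return float(sum(values) / len(values))
    total = float(sum(weights))  # type: ignore[arg-type]
    return float(sum(v * w for v, w in zip(values, weights)) / total)


def _mean_of_available(values: Sequence[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    return float(sum(present) / len(present)) if present else None


def aggregate_populations(
    records: Iterable[SpeciesRecord] | TraitTable,
    weighting: str = "by_sample_size",
) -> TraitTable:
    """Collapse multi-population records to one record per species.

    Entries sharing a (species, population) key — e.g. yearly samples of
    one population — are combined first, weighted by the per-sex sample
    size when ``weighting='by_sample_size'`` and sample sizes are present.
    Across the populations of one species the plain arithmetic mean of the
    population values is then taken, regardless of sample size.

    When ``weighting='by_sample_size'`` but no entry carries a sample
    size, the within-population step falls back to the unweighted mean and
    a warning is logged.
    """
    if weighting not in ("by_sample_size", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    recs = list(records.records if isinstance(records, TraitTable) else records)

    if weighting == "by_sample_size" and all(
        r.female_n is None and r.male_n is None for r in recs
    ):
        logger.warning(
            "weighting='by_sample_size' requested but no record carries a "
            "sample size; falling back to unweighted means"
        )
        weighting = "unweighted"

    # stage 1: combine duplicate (species, population) entries
    by_pop: dict[tuple[str, str | None], list[SpeciesRecord]] = {}
    order: list[tuple[str, str | None]] = []
    for r in recs:
        key = (r.species, r.population)
        if key not in by_pop:
            by_pop[key] = []
            order.append(key)
        by_pop[key].append(r)

    def combine(group: list[SpeciesRecord]) -> SpeciesRecord:
        if len(group) == 1:
            return group[0]
        first = group[0]
        out: dict[str, object] = {
            "species": first.species,
            "population": first.population,
        }
        for sex in ("female", "male"):
            ns = [getattr(g, f"{sex}_n") for g in group]
            use_w = weighting == "by_sample_size" and all(n is not None for n in ns)
            weights = ns if use_w else [None] * len(group)
            out[f"{sex}_size"] = _weighted_mean(
                [getattr(g, f"{sex}_size") for g in group], weights
            )
            ages = [getattr(g, f"{sex}_age") for g in group]
            if all(a is not None for a in ages):
                out[f"{sex}_age"] = _weighted_mean(ages, weights)
            else:
                out[f"{sex}_age"] = _mean_of_available(ages)
            out[f"{sex}_n"] = sum(ns) if all(n is not None for n in ns) else None
        return SpeciesRecord(**out)  # type: ignore[arg-type]

    pop_records = [combine(by_pop[key]) for key in order]

    # stage 2: unweighted mean across populations of one species
    by_species: dict[str, list[SpeciesRecord]] = {}
    sp_order: list[str] = []
    for r in pop_records:
        if r.species not in by_species:
            by_species[r.species] = []
            sp_order.append(r.species)
        by_species[r.species].append(r)

    out_records: list[SpeciesRecord] = []
    for name in sp_order:
        group = by_species[name]
        if len(group) == 1:
            out_records.append(replace(group[0], population=None))
            continue
        kwargs: dict[str, object] = {"species": name, "population": None}
        for fname in ("female_size", "male_size", "female_age", "male_age"):
            kwargs[fname] = _mean_of_available([getattr(g, fname) for g in group])
        for fname in ("female_n", "male_n"):
            ns = [getattr(g, fname) for g in group]
            kwargs[fname] = sum(n for n in ns if n is not None) or None
        out_records.append(SpeciesRecord(**kwargs))  # type: ignore[arg-type]

    return TraitTable(records=out_records, provenance="aggregated")
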