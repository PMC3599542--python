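"""Sexual size dimorphism (SSD) and sexual age difference (SAD) indices.

All indices are signed so that positive values mean female-biased
dimorphism (females larger, or older).  Three SSD variants are offered
because the literature uses several interchangeably:

``lovich_gibbons_ratio``
    (larger size / smaller size) - 1, signed positive when the female is
    the larger sex.  Scale-invariant and symmetric around zero.
``log_ratio_minus_one``
    log10(female size) / log10(male size) - 1.  A ratio of logs; only
    meaningful for sizes away from 1 mm (where log10 = 0).  Default.
``log_difference``
    log10(female size) - log10(male size), i.e. the log of the size ratio.
    Antisymmetric under sex swap and the natural companion of SAD.

SAD is always log10(female age) - log10(male age).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from ._errors import DegenerateInputError, ValidationError
from .table_io import TraitTable

SSD_VARIANTS = ("lovich_gibbons_ratio", "log_ratio_minus_one", "log_difference")
DEFAULT_SSD_VARIANT = "log_ratio_minus_one"

FEMALE_BIASED = "female_biased"
MALE_BIASED = "male_biased"
MONOMORPHIC = "monomorphic"


@dataclass(frozen=True)
class DimorphismRecord:
    """Per-species dimorphism indices and the resulting classification."""

    species: str
    ssd: float
    sad: float | None
    direction: str  # female_biased | male_biased | monomorphic


@dataclass
class ClassificationResult:
    """Per-species records plus direction counts and any per-row failures."""

    records: list[DimorphismRecord]
    counts: dict[str, int]
    errors: list[tuple[str, str]]  # (species, message)


def _check_positive(value: float, name: str) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValidationError(f"{name} must be finite and > 0, got {value!r}")


def compute_ssd(
    female_size: float, male_size: float, variant: str = DEFAULT_SSD_VARIANT
) -> float:
    """Signed sexual size dimorphism index; positive = females larger."""
    _check_positive(female_size, "female_size")
    _check_positive(male_size, "male_size")
    if variant == "lovich_gibbons_ratio":
        if female_size >= male_size:
            return female_size / male_size - 1.0
        return -(male_size / female_size - 1.0)
    if variant == "log_ratio_minus_one":
        log_m = math.log10(male_size)
        if log_m == 0.0:
            raise DegenerateInputError(
                "male_size of exactly 1 mm makes log10(male_size) zero; "
                "the log-ratio SSD variant is undefined there"
            )
        return math.log10(female_size) / log_m - 1.0
    if variant == "log_difference":
        return math.log10(female_size) - math.log10(male_size)
    raise ValueError(f"unknown SSD variant {variant!r}; choose from {SSD_VARIANTS}")


def compute_sad(female_age: float, male_age: float) -> float:
    """log10 female mean age minus log10 male mean age; positive = females older."""
    _check_positive(female_age, "female_age")
    _check_positive(male_age, "male_age")
    return math.log10(female_age) - math.log10(male_age)


def classify_direction(ssd: float, tie_tolerance: float = 0.0) -> str:
    if abs(ssd) <= tie_tolerance:
        return MONOMORPHIC
    return FEMALE_BIASED if ssd > 0 else MALE_BIASED


def classify_table(
    table: TraitTable,
    variant: str = DEFAULT_SSD_VARIANT,
    tie_tolerance: float = 0.0,
) -> ClassificationResult:
    """Compute SSD (and SAD where ages exist) for every species.

    Per-species domain errors (e.g. a 1 mm male under the log-ratio
    variant) are collected in ``errors`` rather than aborting the run.
    """
    records: list[DimorphismRecord] = []
    errors: list[tuple[str, str]] = []
    counts = {FEMALE_BIASED: 0, MALE_BIASED: 0, MONOMORPHIC: 0}
    for rec in table:
        try:
            ssd = compute_ssd(rec.female_size, rec.male_size, variant)
        except (ValidationError, DegenerateInputError) as exc:
            errors.append((rec.species, str(exc)))
            continue
        sad = compute_sad(rec.female_age, rec.male_age) if rec.has_ages else None
        direction = classify_direction(ssd, tie_tolerance)
        counts[direction] += 1
        records.append(DimorphismRecord(rec.species, ssd, sad, direction))
    return ClassificationResult(records=records, counts=counts, errors=errors)
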