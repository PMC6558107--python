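"""Domain types shared across the pipeline.

The pipeline consumes three external inputs: a pairwise in-silico
growth-rate table (single-culture and co-culture growth rates per diet),
per-sample species relative-abundance profiles with patient/control
labels, and a species classification table (commensal / probiotic /
pathogen / opportunistic pathogen).  The types here validate those
inputs once at the boundary so downstream modules can assume clean data.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical diet labels (the growth simulations are run per diet).
WESTERN = "western"
HIGH_FIBER = "high_fiber"

#: Condition labels for abundance profiles.
PATIENT = "patient"
CONTROL = "control"
CONDITIONS = (PATIENT, CONTROL)

#: Species class labels.
COMMENSAL = "commensal"
PROBIOTIC = "probiotic"
PATHOGEN = "pathogen"
OPPORTUNISTIC_PATHOGEN = "opportunistic_pathogen"
SPECIES_CLASSES = (COMMENSAL, PROBIOTIC, PATHOGEN, OPPORTUNISTIC_PATHOGEN)
#: Explicit value returned for species absent from a classification.
UNCLASSIFIED = "unclassified"

#: Directions of abundance change in patients relative to controls.
INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"


class GutnetError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GutnetError):
    """A file does not conform to its documented layout."""


class ValidationError(GutnetError):
    """Data violates a domain invariant."""


class ReconciliationError(GutnetError):
    """Two inputs that must agree (e.g. samples vs. group labels) do not."""


class MappingError(GutnetError):
    """A strain-to-species lookup failed."""


def normalize_id(identifier: str) -> str:
    """Normalize an organism/sample identifier.

    Identifiers are case-sensitive; surrounding whitespace is trimmed and
    internal whitespace collapsed to single underscores so that species
    names written with spaces and with underscores compare equal.
    """
    return re.sub(r"\s+", "_", str(identifier).strip())


@dataclass(frozen=True)
class PairGrowthRecord:
    """Single- and co-culture growth rates for one unordered organism pair.

    ``paired_a`` is the growth rate of ``organism_a`` when co-cultured
    with ``organism_b`` (and symmetrically for ``paired_b``); the
    ``single_*`` rates are growth alone, all in 1/h under one diet.
    """

    organism_a: str
    organism_b: str
    diet: str
    single_a: float
    single_b: float
    paired_a: float
    paired_b: float

    def __post_init__(self) -> None:
        if self.organism_a == self.organism_b:
            raise ValidationError(
                f"self-pair not allowed: {self.organism_a!r}"
            )
        for name in ("single_a", "single_b", "paired_a", "paired_b"):
            rate = getattr(self, name)
            if not math.isfinite(rate):
                raise ValidationError(
                    f"{name} is not finite for pair "
                    f"({self.organism_a}, {self.organism_b})"
                )
            if rate < 0:
                raise ValidationError(
                    f"{name}={rate} is negative for pair "
                    f"({self.organism_a}, {self.organism_b})"
                )

    @property
    def pair_key(self) -> tuple[frozenset, str]:
        return frozenset((self.organism_a, self.organism_b)), self.diet


@dataclass(frozen=True)
class PairTableSummary:
    n_records: int
    n_pairs: int
    diets: tuple[str, ...]


def validate_pair_records(records: Iterable[PairGrowthRecord]) -> PairTableSummary:
    """Check a record collection for duplicate (pair, diet) entries.

    Returns counts: the number of records, the number of distinct
    unordered organism pairs, and the diets present.
    """
    seen: set[tuple[frozenset, str]] = set()
    pairs: set[frozenset] = set()
    diets: set[str] = set()
    n = 0
    for rec in records:
        key = rec.pair_key
        if key in seen:
            raise ValidationError(
                f"duplicate pair ({rec.organism_a}, {rec.organism_b}) "
                f"under diet {rec.diet!r}"
            )
        seen.add(key)
        pairs.add(key[0])
        diets.add(rec.diet)
        n += 1
    return PairTableSummary(n_records=n, n_pairs=len(pairs), diets=tuple(sorted(diets)))


class AbundanceTable:
    """Species-by-sample relative abundances with patient/control labels.

    Abundances are stored internally as fractions in [0, 1]; readers
    accepting percent-scaled tables convert on ingest.  Per-sample sums
    may be below 1 (unclassified mass) but never above 1 + 1e-6.
    """

    SUM_TOL = 1e-6

    def __init__(self, data: pd.DataFrame, groups: Mapping[str, str] | pd.Series):
        data = data.astype(float)
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique())
            raise ValidationError(f"duplicate species identifiers: {dupes}")
        if data.columns.has_duplicates:
            dupes = sorted(data.columns[data.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample identifiers: {dupes}")
        values = data.to_numpy()
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundance table contains non-finite values")
        if (values < 0).any():
            raise ValidationError("abundance table contains negative values")
        sums = values.sum(axis=0)
        bad = np.flatnonzero(sums > 1.0 + self.SUM_TOL)
        if bad.size:
            offender = data.columns[bad[0]]
            raise ValidationError(
                f"sample {offender!r} abundances sum to {sums[bad[0]]:.6g} > 1"
            )
        missing = sorted(set(data.columns) - set(groups.index))
        extra = sorted(set(groups.index) - set(data.columns))
        if missing or extra:
            raise ReconciliationError(
                f"sample/group mismatch: unlabeled samples {missing}, "
                f"labels without samples {extra}"
            )
        bad_labels = sorted(set(groups) - set(CONDITIONS))
        if bad_labels:
            raise ValidationError(f"unknown group labels: {bad_labels}")
        self.data = data
        self.groups = groups.reindex(data.columns)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.groups.index[self.groups == condition])

    def group_values(self, species: str, condition: str) -> np.ndarray:
        """Abundance of one species across the samples of one condition."""
        return self.data.loc[species, self.samples_in(condition)].to_numpy()

    def mean_abundance(self, condition: str) -> pd.Series:
        """Per-species mean relative abundance within one condition."""
        cols = self.samples_in(condition)
        if not cols:
            raise ValidationError(f"no samples labeled {condition!r}")
        return self.data[cols].mean(axis=1)

    def relabeled(self, groups: Mapping[str, str]) -> "AbundanceTable":
        return AbundanceTable(self.data, groups)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"AbundanceTable({len(self.species)} species x "
            f"{len(self.samples)} samples)"
        )


class TaxonClassification:
    """Species -> class lookup with an explicit 'unclassified' miss value."""

    def __init__(self, mapping: Mapping[str, str]):
        clean: dict[str, str] = {}
        for species, cls in mapping.items():
            if cls not in SPECIES_CLASSES:
                raise ValidationError(f"unknown class: {cls}")
            clean[normalize_id(species)] = cls
        self._map = clean

    def class_of(self, species: str) -> str:
        return self._map.get(normalize_id(species), UNCLASSIFIED)

    def species_of_class(self, cls: str) -> list[str]:
        return sorted(s for s, c in self._map.items() if c == cls)

    def items(self):
        return self._map.items()

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, species: str) -> bool:
        return normalize_id(species) in self._map


@dataclass(frozen=True)
class StrainSpeciesMap:
    """Many-to-one strain -> species map bridging growth models (strain
    level) to abundance profiles (species level)."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def identity(cls, organisms: Iterable[str]) -> "StrainSpeciesMap":
        return cls({o: o for o in organisms})

    def species_of(self, strain: str) -> str:
        try:
            return self.mapping[strain]
        except KeyError:
            raise MappingError(f"strain {strain!r} has no species mapping") from None

    def __contains__(self, strain: str) -> bool:
        return strain in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)
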