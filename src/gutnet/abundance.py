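"""Relative-abundance processing: node selection and differential abundance.

Network nodes are the union of the top-k most abundant species (by mean
relative abundance) in patients and in controls; in the source datasets
this union covers more than 90% of total abundance.  Differential
abundance between patients and controls is called per species with a
two-sided Wilcoxon rank-sum test; the direction of change is the sign of
the difference of group medians, assigned independently of significance
because the influence module needs a direction for every species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._stats import benjamini_hochberg, rank_sum_test
from .model import (
    CONTROL,
    DECREASED,
    INCREASED,
    PATIENT,
    UNCHANGED,
    AbundanceTable,
    ValidationError,
)


@dataclass(frozen=True)
class NodeSelection:
    """Union of the per-group top-k species plus coverage bookkeeping."""

    species: tuple[str, ...]
    top_patient: tuple[str, ...]
    top_control: tuple[str, ...]
    #: condition -> summed mean abundance of selected species / total.
    coverage: dict

    def __len__(self) -> int:
        return len(self.species)


def select_network_nodes(table: AbundanceTable, k: int = 50) -> NodeSelection:
    """Select network nodes: union of per-group top-k species by mean abundance.

    Ties at the top-k boundary break lexicographically on species id for
    reproducibility.  If fewer than k species exist, all are returned
    with a warning.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if len(table.species) < k:
        warnings.warn(
            f"table has {len(table.species)} species < k={k}; selecting all",
            stacklevel=2,
        )
    tops: dict[str, tuple[str, ...]] = {}
    means: dict[str, "np.ndarray"] = {}
    for condition in (PATIENT, CONTROL):
        mean = table.mean_abundance(condition)
        ranked = sorted(mean.index, key=lambda s: (-mean[s], s))
        tops[condition] = tuple(ranked[:k])
        means[condition] = mean
    union = tuple(sorted(set(tops[PATIENT]) | set(tops[CONTROL])))
    coverage = {}
    for condition in (PATIENT, CONTROL):
        total = float(means[condition].sum())
        selected = float(means[condition].loc[list(union)].sum())
        coverage[condition] = selected / total if total > 0 else float("nan")
    return NodeSelection(
        species=union,
        top_patient=tops[PATIENT],
        top_control=tops[CONTROL],
        coverage=coverage,
    )


@dataclass(frozen=True)
class DifferentialAbundanceResult:
    species_id: str
    p_value: float
    direction: str  # increased | decreased | unchanged, patients vs controls
    significant: bool
    median_difference: float  # median(patients) - median(controls), fractions
    q_value: float | None = None
    degenerate: bool = False


def differential_abundance(
    table: AbundanceTable, alpha: float = 0.05, adjust: bool = False
) -> list[DifferentialAbundanceResult]:
    """Per-species two-sided rank-sum test of patients vs controls.

    Raw p-values are compared to ``alpha`` by default; ``adjust=True``
    switches significance to Benjamini-Hochberg q-values.  Species absent
    (all-zero) in every sample are flagged degenerate with p = 1.
    """
    patients = table.samples_in(PATIENT)
    controls = table.samples_in(CONTROL)
    if len(patients) < 2 or len(controls) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(patients)} patients / "
            f"{len(controls)} controls"
        )
    rows = []
    for species in table.species:
        x = table.group_values(species, PATIENT)
        y = table.group_values(species, CONTROL)
        degenerate = bool(np.all(x == 0) and np.all(y == 0))
        res = rank_sum_test(x, y)
        diff = float(np.median(x) - np.median(y))
        if diff > 0:
            direction = INCREASED
        elif diff < 0:
            direction = DECREASED
        else:
            direction = UNCHANGED
        rows.append((species, res.p_value, direction, diff, degenerate))
    p_values = np.array([r[1] for r in rows])
    q_values = benjamini_hochberg(p_values) if adjust else [None] * len(rows)
    out = []
    for (species, p, direction, diff, degenerate), q in zip(rows, q_values):
        decisive = q if adjust else p
        out.append(
            DifferentialAbundanceResult(
                species_id=species,
                p_value=float(p),
                direction=direction,
                significant=bool(decisive < alpha),
                median_difference=diff,
                q_value=None if q is None else float(q),
                degenerate=degenerate,
            )
        )
    return out


def observed_directions(
    results: list[DifferentialAbundanceResult], significant_only: bool = False
) -> dict:
    """species -> direction map from differential-abundance results."""
    return {
        r.species_id: r.direction
        for r in results
        if not significant_only or r.significant
    }
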