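"""Directed interaction weights from pairwise growth rates.

The metabolic dependency of organism *i* on organism *j* is quantified as
w(i<-j) = log2(P/S), where P is the growth rate of *i* co-cultured with
*j* and S its growth rate alone.  w > 0 means *j* promotes the growth of
*i*, w < 0 means inhibition, w = 0 means no change.  Each unordered pair
therefore yields two directed weights, one per direction.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .model import (
    MappingError,
    PairGrowthRecord,
    StrainSpeciesMap,
    ValidationError,
)

#: Weight assigned when the paired growth rate is exactly zero
#: (extinction in co-culture); log2 would be -inf.  Clamped entries are
#: flagged so downstream statistics can audit them.
DEFAULT_FLOOR = -10.0


def compute_weight(paired: float, single: float, floor: float = DEFAULT_FLOOR) -> float:
    """log2 growth-rate change of one organism caused by its partner.

    Parameters
    ----------
    paired
        Growth rate co-cultured with the partner (1/h, >= 0).
    single
        Growth rate alone (1/h, must be > 0: the baseline).
    floor
        Value returned when ``paired`` is 0 (log2 is -infinity).
    """
    if not math.isfinite(single) or single <= 0:
        raise ValidationError(f"single growth rate must be > 0, got {single}")
    if not math.isfinite(paired) or paired < 0:
        raise ValidationError(f"paired growth rate must be >= 0, got {paired}")
    if paired == 0:
        return float(floor)
    return math.log2(paired / single)


@dataclass(frozen=True)
class InteractionMatrix:
    """Directed weights for one diet, keyed (target, source).

    ``weights[(i, j)]`` is the growth change of *i* caused by *j*.
    Lookup of an absent ordered pair raises ``KeyError``: absence means
    "not simulated", never "no interaction".
    """

    diet: str
    weights: Mapping[tuple[str, str], float]
    clamped: frozenset = field(default_factory=frozenset)

    @property
    def organisms(self) -> set[str]:
        out: set[str] = set()
        for target, source in self.weights:
            out.add(target)
            out.add(source)
        return out

    def get(self, target: str, source: str) -> float:
        try:
            return self.weights[(target, source)]
        except KeyError:
            raise KeyError(
                f"no interaction recorded for {target!r} <- {source!r} "
                f"under diet {self.diet!r}"
            ) from None

    def is_clamped(self, target: str, source: str) -> bool:
        return (target, source) in self.clamped

    def items(self):
        return self.weights.items()

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.weights

    def __len__(self) -> int:
        return len(self.weights)


def build_interaction_matrix(
    records: Iterable[PairGrowthRecord],
    diet: str,
    floor: float = DEFAULT_FLOOR,
) -> InteractionMatrix:
    """Assemble the directed weight matrix for one diet.

    Each record contributes two entries: w(a<-b) from (paired_a,
    single_a) and w(b<-a) from (paired_b, single_b).
    """
    weights: dict[tuple[str, str], float] = {}
    clamped: set[tuple[str, str]] = set()
    for rec in records:
        if rec.diet != diet:
            continue
        a, b = rec.organism_a, rec.organism_b
        weights[(a, b)] = compute_weight(rec.paired_a, rec.single_a, floor)
        weights[(b, a)] = compute_weight(rec.paired_b, rec.single_b, floor)
        if rec.paired_a == 0:
            clamped.add((a, b))
        if rec.paired_b == 0:
            clamped.add((b, a))
    if not weights:
        raise ValidationError(f"no records for diet {diet!r}")
    return InteractionMatrix(diet=diet, weights=weights, clamped=frozenset(clamped))


def aggregate_to_species(
    matrix: InteractionMatrix, strain_map: StrainSpeciesMap | Mapping[str, str]
) -> InteractionMatrix:
    """Collapse a strain-level matrix to species level.

    The species-level weight w(X<-Y) is the arithmetic mean of the
    strain-level weights over every ordered (strain of X, strain of Y)
    pair present.  Pairs of distinct strains of the same species are
    dropped (a species does not interact with itself here).  An entry is
    flagged clamped if any contributing strain entry was.
    """
    mapping = strain_map.mapping if isinstance(strain_map, StrainSpeciesMap) else strain_map
    unmapped = sorted(matrix.organisms - set(mapping))
    if unmapped:
        raise MappingError(f"organisms without species mapping: {unmapped}")
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    clamped: set[tuple[str, str]] = set()
    for (target, source), w in matrix.items():
        key = (mapping[target], mapping[source])
        if key[0] == key[1]:
            continue
        sums[key] = sums.get(key, 0.0) + w
        counts[key] = counts.get(key, 0) + 1
        if matrix.is_clamped(target, source):
            clamped.add(key)
    weights = {key: sums[key] / counts[key] for key in sums}
    return InteractionMatrix(diet=matrix.diet, weights=weights, clamped=frozenset(clamped))
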