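"""Inbound Influence Index and direction-of-change prediction.

For a species s in the dependency network, the Inbound Influence Index
under one condition is

    II(s) = sum over inbound neighbors j of  w(s<-j) * a_j

where w(s<-j) is the signed edge weight (the log2 growth change of s
caused by j) and a_j is neighbor j's mean relative abundance in that
condition.  Comparing the index between patients and controls gives a
predicted direction of abundance change for s, scored against the
direction observed by differential abundance.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd

from .abundance import DifferentialAbundanceResult
from .model import (
    CONTROL,
    DECREASED,
    INCREASED,
    PATIENT,
    UNCHANGED,
    AbundanceTable,
    ValidationError,
)
from .network import DependencyNetwork

MODE_DELTA = "delta"  # predict from sign(II_patient - II_control)
MODE_STATIC = "static"  # predict from sign(II_control)


def inbound_influence(
    network: DependencyNetwork, species: str, abundances: Mapping
) -> float:
    """II of one species: sum of signed inbound weights times neighbor abundance.

    Neighbors missing from ``abundances`` contribute 0 (profilers emit
    zeros by omission).  A species not in the network is a lookup error.
    """
    G = network.graph
    if species not in G:
        raise KeyError(f"species {species!r} is not a network node")
    return float(
        sum(
            data["signed_w"] * float(abundances.get(j, 0.0))
            for j, _, data in G.in_edges(species, data=True)
        )
    )


def influence_table(
    network: DependencyNetwork,
    abundance: AbundanceTable,
    mode: str = MODE_DELTA,
) -> pd.DataFrame:
    """Per-node II under both conditions plus the predicted direction.

    Columns: II_control, II_patient, delta_II, predicted, tie.  The
    decision statistic is delta_II (mode "delta", default) or II_control
    (mode "static"); a positive statistic predicts "increased", negative
    "decreased", and an exact zero resolves deterministically to
    "decreased" with the tie flagged.
    """
    if mode not in (MODE_DELTA, MODE_STATIC):
        raise ValidationError(f"unknown prediction mode {mode!r}")
    a_control = abundance.mean_abundance(CONTROL)
    a_patient = abundance.mean_abundance(PATIENT)
    rows = []
    for species in sorted(network.graph.nodes):
        ii_c = inbound_influence(network, species, a_control)
        ii_p = inbound_influence(network, species, a_patient)
        delta = ii_p - ii_c
        statistic = delta if mode == MODE_DELTA else ii_c
        predicted = INCREASED if statistic > 0 else DECREASED
        rows.append(
            {
                "species": species,
                "II_control": ii_c,
                "II_patient": ii_p,
                "delta_II": delta,
                "predicted": predicted,
                "tie": statistic == 0,
            }
        )
    return pd.DataFrame(rows).set_index("species")


def predict_directions(table: pd.DataFrame) -> dict:
    """species -> predicted direction from an influence table."""
    return table["predicted"].to_dict()


@dataclass(frozen=True)
class AccuracyResult:
    n_match: int
    n_evaluated: int
    n_ties: int

    @property
    def accuracy(self) -> float:
        return self.n_match / self.n_evaluated


def score_accuracy(
    predicted: Mapping,
    observed,
    ties: Mapping | None = None,
) -> AccuracyResult:
    """Fraction of species whose predicted direction matches the observed one.

    ``observed`` is either a species -> direction mapping or an iterable
    of differential-abundance results.  Species observed as unchanged
    (or absent from the predictions) are excluded from the denominator.
    """
    if not isinstance(observed, Mapping):
        observed = {
            r.species_id: r.direction
            for r in observed
            if isinstance(r, DifferentialAbundanceResult)
        }
    n_match = n_eval = n_ties = 0
    for species, direction in observed.items():
        if direction == UNCHANGED or species not in predicted:
            continue
        n_eval += 1
        if predicted[species] == direction:
            n_match += 1
        if ties is not None and ties.get(species, False):
            n_ties += 1
    if n_eval == 0:
        raise ValidationError("accuracy undefined: no evaluable species")
    return AccuracyResult(n_match=n_match, n_evaluated=n_eval, n_ties=n_ties)
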