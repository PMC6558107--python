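"""Synthetic study generator with known planted structure.

Emulates the three inputs of the pipeline — a pairwise growth-rate
table, abundance profiles with patient/control labels, and a species
classification — so every stage is testable without external data.
Interaction effects are planted on the log2 weight scale (directly
comparable to the network edge threshold), reproducing the asserted
structure of the real data: mutual inhibition among probiotics (and
inhibition of probiotics by others), mutual promotion among
disease-enriched species (which also promote others).

Two modes generate differential species:

* ``independent`` — a designated enriched set gets a fixed abundance
  fold-change in patients; tests differential abundance and the
  four-group statistics in isolation.
* ``ii_driven`` — abundance changes are wired to the interaction
  network itself: planted super-threshold "driver -> responder" edges
  determine each responder's direction via the sign of its inbound
  influence change, with an independent per-species noise rate ``q``
  flipping directions.  Drivers (which have no inbound edges, hence a
  zero influence index) all decrease.  At q = 0 the inbound-influence
  predictor is correct by construction for every species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .model import (
    CONTROL,
    DECREASED,
    INCREASED,
    PATIENT,
    PROBIOTIC,
    UNCHANGED,
    WESTERN,
    AbundanceTable,
    PairGrowthRecord,
    StrainSpeciesMap,
    TaxonClassification,
    ValidationError,
)
from .weights import aggregate_to_species, build_interaction_matrix

MODE_INDEPENDENT = "independent"
MODE_II_DRIVEN = "ii_driven"

# fixed spawn order of the per-component random streams; adding samples
# must not perturb the growth table
_STREAMS = ("classification", "enriched", "growth", "abundance", "noise")


@dataclass(frozen=True)
class Scenario:
    """Parameters of one synthetic study.

    Weight shifts are in log2 units and additive when several rules
    match an ordered species pair; abundances are lognormal with a
    per-sample multiplicative noise; ``direction_noise`` (q) only acts
    in ``ii_driven`` mode.
    """

    n_species: int = 50
    n_strains_per_species: int = 1
    frac_probiotic: float = 0.2
    frac_pathogen: float = 0.1
    frac_commensal: float = 0.6
    n_enriched: int = 10
    n_samples_per_group: int = 20
    diets: tuple = (WESTERN,)
    # interaction weights
    sigma_w: float = 1.0
    delta_within_probiotic: float = -2.0
    delta_within_enriched: float = 2.0
    delta_affected_probiotic: float = -2.0
    delta_affecting_enriched: float = 2.0
    single_rate_mu: float = -0.7  # log of ~0.5 1/h
    single_rate_sigma: float = 0.3
    # abundances
    base_abundance_sigma: float = 1.0
    sample_sigma: float = 0.5
    fold_change: float = 4.0
    direction_noise: float = 0.0
    # ii_driven wiring
    mode: str = MODE_INDEPENDENT
    driver_fraction: float = 0.3
    planted_edge_weight: float = 6.0
    edge_threshold: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.n_strains_per_species < 1:
            raise ValidationError("n_strains_per_species must be >= 1")
        fracs = (self.frac_probiotic, self.frac_pathogen, self.frac_commensal)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValidationError("class fractions must be >= 0 and sum to <= 1")
        if self.n_samples_per_group < 2:
            raise ValidationError("n_samples_per_group must be >= 2")
        if not self.diets:
            raise ValidationError("at least one diet label required")
        if self.sigma_w < 0 or self.sample_sigma < 0 or self.base_abundance_sigma < 0:
            raise ValidationError("scale parameters must be >= 0")
        if not 0 <= self.direction_noise <= 1:
            raise ValidationError("direction_noise must be in [0, 1]")
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be > 0")
        if self.mode not in (MODE_INDEPENDENT, MODE_II_DRIVEN):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not 0 < self.driver_fraction < 1:
            raise ValidationError("driver_fraction must be in (0, 1)")
        if self.planted_edge_weight <= self.edge_threshold:
            raise ValidationError("planted_edge_weight must exceed edge_threshold")


def _rng(scenario: Scenario, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(scenario.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


def species_ids(scenario: Scenario) -> list[str]:
    return [f"sp{i:04d}" for i in range(scenario.n_species)]


def generate_classification(scenario: Scenario) -> tuple[TaxonClassification, StrainSpeciesMap]:
    """Assign classes by the scenario fractions and name strains.

    Class counts are round(fraction * n) for probiotic, pathogen and
    commensal in that order; the remainder is opportunistic pathogen
    (a rounding overshoot is absorbed by the commensal count).
    Assignment to species is a seeded permutation.
    """
    n = scenario.n_species
    n_p = round(scenario.frac_probiotic * n)
    n_d = round(scenario.frac_pathogen * n)
    n_c = round(scenario.frac_commensal * n)
    n_o = n - (n_p + n_d + n_c)
    if n_o < 0:
        n_c += n_o
        n_o = 0
    rng = _rng(scenario, "classification")
    order = rng.permutation(species_ids(scenario))
    mapping: dict[str, str] = {}
    labels = (
        ["probiotic"] * n_p + ["pathogen"] * n_d + ["commensal"] * n_c
        + ["opportunistic_pathogen"] * n_o
    )
    for species, label in zip(order, labels):
        mapping[species] = label
    strains = {
        f"{sp}_t{k + 1}": sp
        for sp in species_ids(scenario)
        for k in range(scenario.n_strains_per_species)
    }
    return TaxonClassification(mapping), StrainSpeciesMap(strains)


def enriched_species(scenario: Scenario) -> tuple[str, ...]:
    """The designated disease-enriched species (never probiotics)."""
    classes, _ = generate_classification(scenario)
    candidates = sorted(
        sp for sp in species_ids(scenario) if classes.class_of(sp) != PROBIOTIC
    )
    k = min(scenario.n_enriched, len(candidates))
    rng = _rng(scenario, "enriched")
    chosen = rng.choice(candidates, size=k, replace=False)
    return tuple(sorted(chosen))


def _planted_shift(
    scenario: Scenario,
    source_sp: str,
    target_sp: str,
    classes: TaxonClassification,
    enriched: set,
) -> float:
    shift = 0.0
    src_prob = classes.class_of(source_sp) == PROBIOTIC
    tgt_prob = classes.class_of(target_sp) == PROBIOTIC
    if src_prob and tgt_prob:
        shift += scenario.delta_within_probiotic
    if not src_prob and tgt_prob:
        shift += scenario.delta_affected_probiotic
    if source_sp in enriched and target_sp in enriched:
        shift += scenario.delta_within_enriched
    if source_sp in enriched and target_sp not in enriched:
        shift += scenario.delta_affecting_enriched
    return shift


def _ii_design(scenario: Scenario, rng: np.random.Generator) -> dict:
    """Planted driver->responder edges for ii_driven mode.

    Keys (target_species, source_species) -> signed weight of magnitude
    ``planted_edge_weight``; every responder gets exactly one driver.
    """
    species = species_ids(scenario)
    n_drivers = max(1, round(scenario.driver_fraction * len(species)))
    order = list(rng.permutation(species))
    drivers = sorted(order[:n_drivers])
    responders = sorted(order[n_drivers:])
    planted: dict[tuple[str, str], float] = {}
    for responder in responders:
        driver = str(rng.choice(drivers))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        planted[(responder, driver)] = sign * scenario.planted_edge_weight
    return planted


def generate_growth_table(scenario: Scenario) -> list[PairGrowthRecord]:
    """Emit single/paired growth rates whose recomputed weights carry the
    planted group shifts (independent mode) or the planted driver edges
    on a sub-threshold baseline (ii_driven mode)."""
    classes, strain_map = generate_classification(scenario)
    enriched = set(enriched_species(scenario))
    rng = _rng(scenario, "growth")
    strains = sorted(strain_map.mapping)
    pairs = list(combinations(strains, 2))
    records: list[PairGrowthRecord] = []
    planted = _ii_design(scenario, rng) if scenario.mode == MODE_II_DRIVEN else {}
    cap = scenario.edge_threshold - 0.1
    for diet in scenario.diets:
        singles = dict(
            zip(
                strains,
                rng.lognormal(
                    scenario.single_rate_mu, scenario.single_rate_sigma, len(strains)
                ),
            )
        )
        noise = rng.normal(0.0, scenario.sigma_w, size=(len(pairs), 2)) \
            if scenario.sigma_w > 0 else np.zeros((len(pairs), 2))
        for (a, b), (eps_a, eps_b) in zip(pairs, noise):
            sp_a = strain_map.species_of(a)
            sp_b = strain_map.species_of(b)
            if scenario.mode == MODE_II_DRIVEN:
                # baseline stays strictly below the edge threshold so the
                # only super-threshold edges are the planted ones
                w_a = float(np.clip(eps_a, -cap, cap))
                w_b = float(np.clip(eps_b, -cap, cap))
                if (sp_a, sp_b) in planted:
                    w_a = planted[(sp_a, sp_b)]
                if (sp_b, sp_a) in planted:
                    w_b = planted[(sp_b, sp_a)]
            else:
                w_a = _planted_shift(scenario, sp_b, sp_a, classes, enriched) + eps_a
                w_b = _planted_shift(scenario, sp_a, sp_b, classes, enriched) + eps_b
            records.append(
                PairGrowthRecord(
                    organism_a=a,
                    organism_b=b,
                    diet=diet,
                    single_a=float(singles[a]),
                    single_b=float(singles[b]),
                    paired_a=float(singles[a] * 2.0 ** w_a),
                    paired_b=float(singles[b] * 2.0 ** w_b),
                )
            )
    return records


def generate_abundance(
    scenario: Scenario, growth_table: list[PairGrowthRecord] | None = None
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Sample abundance profiles plus the planted ground truth.

    Returns the table (per-sample renormalized fractions) and a truth
    frame indexed by species with columns ``fold`` (patient/control mean
    ratio before renormalization) and ``direction``.
    """
    species = species_ids(scenario)
    n = len(species)
    rng = _rng(scenario, "abundance")
    rng_noise = _rng(scenario, "noise")
    base = rng.lognormal(0.0, scenario.base_abundance_sigma, n)
    base_frac = base / base.sum()
    folds = pd.Series(1.0, index=species)
    F = scenario.fold_change
    q = scenario.direction_noise
    if scenario.mode == MODE_INDEPENDENT:
        for sp in enriched_species(scenario):
            folds[sp] = F
    else:
        if growth_table is None:
            growth_table = generate_growth_table(scenario)
        _, strain_map = generate_classification(scenario)
        matrix = aggregate_to_species(
            build_interaction_matrix(growth_table, scenario.diets[0]), strain_map
        )
        inbound: dict[str, list[tuple[str, float]]] = {sp: [] for sp in species}
        for (target, source), w in matrix.items():
            if abs(w) > scenario.edge_threshold:
                inbound[target].append((source, w))
        drivers = sorted(sp for sp in species if not inbound[sp])
        responders = sorted(sp for sp in species if inbound[sp])
        for sp in drivers:
            folds[sp] = 1.0 / F
            if q > 0 and rng_noise.random() < q:
                folds[sp] = F
        base_lookup = dict(zip(species, base_frac))
        for sp in responders:
            delta_ii = sum(
                w * base_lookup[j] * (folds[j] - 1.0) for j, w in inbound[sp]
            )
            if delta_ii > 0:
                folds[sp] = F
            elif delta_ii < 0:
                folds[sp] = 1.0 / F
            if q > 0 and rng_noise.random() < q and folds[sp] != 1.0:
                folds[sp] = 1.0 / folds[sp]
    m = scenario.n_samples_per_group
    noise_c = rng.lognormal(0.0, scenario.sample_sigma, (n, m)) \
        if scenario.sample_sigma > 0 else np.ones((n, m))
    noise_p = rng.lognormal(0.0, scenario.sample_sigma, (n, m)) \
        if scenario.sample_sigma > 0 else np.ones((n, m))
    control = base[:, None] * noise_c
    patient = (base * folds.to_numpy())[:, None] * noise_p
    control /= control.sum(axis=0, keepdims=True)
    patient /= patient.sum(axis=0, keepdims=True)
    samples = [f"ctrl{i + 1:03d}" for i in range(m)] + [
        f"pat{i + 1:03d}" for i in range(m)
    ]
    frame = pd.DataFrame(
        np.hstack([control, patient]), index=species, columns=samples
    )
    groups = {s: (CONTROL if s.startswith("ctrl") else PATIENT) for s in samples}
    direction = folds.map(
        lambda f: INCREASED if f > 1 else (DECREASED if f < 1 else UNCHANGED)
    )
    truth = pd.DataFrame({"fold": folds, "direction": direction})
    truth.index.name = "species"
    return AbundanceTable(frame, groups), truth


@dataclass
class SyntheticDataset:
    scenario: Scenario
    classification: TaxonClassification
    strain_map: StrainSpeciesMap
    enriched: tuple
    records: list = field(default_factory=list)
    abundance: AbundanceTable | None = None
    truth: pd.DataFrame | None = None


def simulate(scenario: Scenario) -> SyntheticDataset:
    """Generate a complete synthetic study."""
    classification, strain_map = generate_classification(scenario)
    records = generate_growth_table(scenario)
    abundance, truth = generate_abundance(scenario, records)
    return SyntheticDataset(
        scenario=scenario,
        classification=classification,
        strain_map=strain_map,
        enriched=enriched_species(scenario),
        records=records,
        abundance=abundance,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write a dataset to a directory; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pairs": outdir / "pairs.tsv",
        "abundance": outdir / "abundance.tsv",
        "groups": outdir / "groups.tsv",
        "classes": outdir / "classes.tsv",
        "strain_map": outdir / "strain_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    gio.write_pair_growth_table(dataset.records, paths["pairs"])
    gio.write_abundance_table(dataset.abundance, paths["abundance"], paths["groups"])
    gio.write_classification(dataset.classification, paths["classes"])
    gio.write_strain_map(dataset.strain_map, paths["strain_map"])
    dataset.truth.to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def scenario_from_dict(config: dict) -> Scenario:
    """Build a scenario from a (YAML-loaded) mapping, defaulting missing keys."""
    known = {f for f in Scenario.__dataclass_fields__}
    unknown = sorted(set(config) - known)
    if unknown:
        raise ValidationError(f"unknown scenario fields: {unknown}")
    if "diets" in config:
        config = dict(config, diets=tuple(config["diets"]))
    return replace(Scenario(), **config)
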