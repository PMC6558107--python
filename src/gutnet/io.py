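"""Readers and writers for every external format the pipeline touches.

All tabular files are UTF-8, tab-delimited; lines starting with '#' are
comments (except a '#'-prefixed header on the very first line, which
MetaPhlAn merged tables use).  Networks export to GraphML (lossless
round-trip), GEXF, or a flat edge TSV.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .model import (
    AbundanceTable,
    FormatError,
    PairGrowthRecord,
    ReconciliationError,
    StrainSpeciesMap,
    TaxonClassification,
    ValidationError,
    normalize_id,
    validate_pair_records,
)
from .network import DependencyNetwork

logger = logging.getLogger(__name__)

PAIR_COLUMNS = (
    "organism_a",
    "organism_b",
    "diet",
    "single_a",
    "single_b",
    "paired_a",
    "paired_b",
)


def _read_rows(path) -> list[tuple[int, list[str]]]:
    """Tab-split rows with 1-based line numbers, comments/blanks skipped.

    A '#'-prefixed first line is kept (stripped of the '#') so MetaPhlAn
    style headers survive.
    """
    rows = []
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                if lineno != 1:
                    continue
                line = line.lstrip("#")
            rows.append((lineno, line.split("\t")))
    return rows


def read_pair_growth_table(path) -> list[PairGrowthRecord]:
    """Read and validate a pair-growth TSV (header mandatory).

    Columns: organism_a, organism_b, diet, single_a, single_b, paired_a,
    paired_b.  Duplicate (pair, diet) rows and negative or non-numeric
    rates are rejected with the offending line number.
    """
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = [c.strip() for c in rows[0][1]]
    missing = [c for c in PAIR_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in PAIR_COLUMNS}
    records = []
    for lineno, fields in rows[1:]:
        if len(fields) < len(header):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
        rates = {}
        for col in ("single_a", "single_b", "paired_a", "paired_b"):
            raw = fields[idx[col]]
            try:
                rates[col] = float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric {col}: {raw!r}"
                ) from None
        try:
            records.append(
                PairGrowthRecord(
                    organism_a=normalize_id(fields[idx["organism_a"]]),
                    organism_b=normalize_id(fields[idx["organism_b"]]),
                    diet=fields[idx["diet"]].strip(),
                    **rates,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}:{lineno}: {err}") from None
    summary = validate_pair_records(records)
    logger.info(
        "read %d pair-growth records (%d pairs, diets %s) from %s",
        summary.n_records, summary.n_pairs, list(summary.diets), path,
    )
    return records


def write_pair_growth_table(records, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PAIR_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.organism_a,
                    rec.organism_b,
                    rec.diet,
                    repr(float(rec.single_a)),
                    repr(float(rec.single_b)),
                    repr(float(rec.paired_a)),
                    repr(float(rec.paired_b)),
                ]
            )


def _read_two_column(path, what: str) -> list[tuple[str, str]]:
    rows = _read_rows(path)
    out = []
    for lineno, fields in rows:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns for {what}")
        out.append((fields[0].strip(), fields[1].strip()))
    return out


def read_sample_groups(path) -> dict:
    """Two-column sample -> group (patient/control) TSV, header optional."""
    pairs = _read_two_column(path, "sample groups")
    if pairs and pairs[0][1].lower() in ("group", "label", "condition"):
        pairs = pairs[1:]
    return {normalize_id(s): g.lower() for s, g in pairs}


def read_abundance_table(
    path,
    groups_path,
    fmt: str = "metaphlan_merged",
    scale: str = "percent",
) -> AbundanceTable:
    """Read a per-sample species relative-abundance table.

    ``metaphlan_merged``: first column is the pipe-delimited lineage;
    only rows whose lineage terminates at species level (last field
    ``s__...``, no strain level) are retained, and the species id is the
    ``s__`` token.  ``plain_tsv``: first column is the species id.
    ``scale`` declares whether values are percentages (0-100) or
    fractions (0-1); storage is always fractional.
    """
    if fmt not in ("metaphlan_merged", "plain_tsv"):
        raise ValidationError(f"unknown abundance format {fmt!r}")
    if scale not in ("percent", "fraction"):
        raise ValidationError(f"unknown scale {scale!r}")
    rows = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0][1]
    samples = [normalize_id(s) for s in header[1:]]
    data: dict[str, list[float]] = {}
    for lineno, fields in rows[1:]:
        label = fields[0]
        if fmt == "metaphlan_merged":
            parts = label.split("|")
            if not parts[-1].startswith("s__"):
                continue
            species = normalize_id(parts[-1][len("s__"):])
        else:
            species = normalize_id(label)
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric abundance") from None
        if species in data:
            raise ValidationError(f"{path}:{lineno}: duplicate species {species!r}")
        data[species] = values
    if not data:
        raise FormatError(f"{path}: no species-level rows found")
    frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    if scale == "percent":
        frame = frame / 100.0
    groups = read_sample_groups(groups_path)
    missing = sorted(set(groups) - set(samples))
    if missing:
        raise ReconciliationError(
            f"samples in group mapping absent from table: {missing}"
        )
    return AbundanceTable(frame, groups)


def write_abundance_table(table: AbundanceTable, path, groups_path=None) -> None:
    """Write a plain TSV abundance table (fractions) and optional groups file."""
    out = table.data.copy()
    out.index.name = "species"
    out.to_csv(path, sep="\t", float_format="%.12g")
    if groups_path is not None:
        with open(groups_path, "w", encoding="utf-8") as handle:
            handle.write("sample\tgroup\n")
            for sample, group in table.groups.items():
                handle.write(f"{sample}\t{group}\n")


def read_classification(path) -> TaxonClassification:
    """Two-column species -> class TSV; class names are case-insensitive
    with spaces allowed ("Opportunistic pathogen")."""
    pairs = _read_two_column(path, "classification") if Path(path).stat().st_size else []
    if pairs and pairs[0][1].lower() in ("class", "classification"):
        pairs = pairs[1:]
    if not pairs:
        logger.warning("classification file %s is empty", path)
        return TaxonClassification({})
    mapping = {
        species: normalize_id(cls).lower() for species, cls in pairs
    }
    return TaxonClassification(mapping)


def write_classification(classes: TaxonClassification, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("species\tclass\n")
        for species, cls in sorted(classes.items()):
            handle.write(f"{species}\t{cls}\n")


def read_strain_map(path) -> StrainSpeciesMap:
    pairs = _read_two_column(path, "strain map")
    if pairs and pairs[0][1].lower() in ("species", "species_id"):
        pairs = pairs[1:]
    mapping: dict[str, str] = {}
    for strain, species in pairs:
        strain = normalize_id(strain)
        species = normalize_id(species)
        if strain in mapping and mapping[strain] != species:
            raise ValidationError(
                f"strain {strain!r} maps to both {mapping[strain]!r} and {species!r}"
            )
        mapping[strain] = species
    return StrainSpeciesMap(mapping)


def write_strain_map(strain_map: StrainSpeciesMap, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("strain\tspecies\n")
        for strain, species in sorted(strain_map.mapping.items()):
            handle.write(f"{strain}\t{species}\n")


NETWORK_FORMATS = ("graphml", "gexf", "edge_tsv")
_GRAPH_META = ("condition", "diet", "threshold")


def write_network(network: DependencyNetwork, path, fmt: str = "graphml") -> None:
    """Export a dependency network (GraphML round-trips losslessly)."""
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"unknown network format {fmt!r}")
    G = network.graph.copy()
    G.graph.update(
        condition=network.condition, diet=network.diet, threshold=network.threshold
    )
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        nx.write_gexf(G, path)
    else:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("source\ttarget\tsigned_w\tmagnitude\tsign\n")
            for u, v, data in sorted(G.edges(data=True)):
                handle.write(
                    f"{u}\t{v}\t{data['signed_w']!r}\t{data['magnitude']!r}"
                    f"\t{data['sign']}\n"
                )


def read_network(path) -> DependencyNetwork:
    """Read a GraphML dependency network written by :func:`write_network`."""
    G = nx.read_graphml(path)
    if not isinstance(G, nx.DiGraph):
        G = G.to_directed()
    meta = {key: G.graph.pop(key, None) for key in _GRAPH_META}
    return DependencyNetwork(
        graph=G,
        condition=meta["condition"] or "",
        diet=meta["diet"] or "",
        threshold=float(meta["threshold"]) if meta["threshold"] is not None else 0.0,
    )
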