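"""Readers and writers for the pipeline's external file formats.

Dialects (all tab-separated, UTF-8, header rows required):

* expression matrix — row 1 ``gene_id`` + sample ids, one gene per row;
* sample sheet — columns ``sample_id  species  stage  replicate``;
* ortholog map — two columns ``gene_a  gene_b``; the header row is always skipped;
* gene sets — standard GMT (name, description, then members);
* result tables — TSV with header, floats at 6 significant digits.

Values are assumed already log2-summarized upstream (e.g. by RMA); no
transformation is applied on load, and empty cells are parse errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionDataset,
    FormatError,
    GeneSetCollection,
    OrthologMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "load_ortholog_map",
    "load_gene_sets",
    "write_table",
    "read_table",
]


def load_expression(matrix_path, sample_sheet_path) -> ExpressionDataset:
    """Load a log2 expression matrix plus its sample sheet into a validated dataset.

    Every matrix column must appear in the sheet; the dataset keeps the
    matrix file's column order. Raises :class:`FormatError` on dialect
    violations and :class:`ValidationError` on semantic ones (unknown stage,
    duplicate replicate, non-numeric cell).
    """
    matrix_path = Path(matrix_path)
    sheet_path = Path(sample_sheet_path)

    raw = pd.read_csv(matrix_path, sep="\t", dtype=str)
    if raw.shape[1] < 2 or raw.columns[0] != "gene_id":
        raise FormatError(
            f"{matrix_path}: expected header starting with 'gene_id' and >=1 sample column"
        )
    gene_ids = raw["gene_id"].astype(str)
    if gene_ids.isna().any() or (gene_ids.str.strip() == "").any():
        raise FormatError(f"{matrix_path}: empty gene identifier")
    values = raw.drop(columns=["gene_id"])
    numeric = pd.DataFrame(index=gene_ids, columns=values.columns, dtype=float)
    for col in values.columns:
        converted = pd.to_numeric(values[col], errors="coerce")
        bad = converted.isna() | values[col].isna()
        if bad.any():
            row = gene_ids[bad.to_numpy()].iloc[0]
            raise FormatError(
                f"{matrix_path}: non-numeric or empty cell at gene {row!r}, column {col!r}"
            )
        numeric[col] = converted.to_numpy()

    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = ["sample_id", "species", "stage", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise FormatError(f"{sheet_path}: sample sheet missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{sheet_path}: duplicate sample_id(s) {dupes}")

    sheet_ids = set(sheet["sample_id"])
    absent = [c for c in numeric.columns if c not in sheet_ids]
    if absent:
        raise FormatError(f"{sheet_path}: matrix column(s) {absent} absent from sample sheet")

    species = sheet["species"].unique()
    if len(species) != 1:
        raise FormatError(f"{sheet_path}: sample sheet must describe one species, got {list(species)}")

    try:
        replicate = sheet["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{sheet_path}: non-integer replicate value") from exc
    sheet = sheet.assign(replicate=replicate)

    # keep sheet rows in matrix column order, dropping any extra sheet rows
    sheet = sheet.set_index("sample_id").loc[list(numeric.columns)].reset_index()
    return ExpressionDataset(species_label=str(species[0]), values=numeric, samples=sheet)


def load_ortholog_map(path) -> OrthologMap:
    """Load a two-column ortholog translation table (header row always skipped).

    Duplicate rows collapse to one pair; many-to-many links are preserved.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise FormatError(f"{path}: empty ortholog file")
    header = text[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: ortholog table needs >=2 tab-separated columns")
    pairs = set()
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}:{lineno}: expected two non-empty identifiers")
        pairs.add((fields[0].strip(), fields[1].strip()))
    if not pairs:
        raise FormatError(f"{path}: no data rows after header")
    omap = OrthologMap.from_pairs(pairs)
    logger.info(
        "ortholog map: %d pairs, %d distinct species-A genes, %d distinct species-B genes",
        len(omap), len(omap.genes_a), len(omap.genes_b),
    )
    return omap


def load_gene_sets(path) -> GeneSetCollection:
    """Load a GMT file: name, description, members per line; members de-duplicated."""
    path = Path(path)
    sets: dict[str, set] = {}
    provenance: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields (name, description, members)")
        name, desc, *members = fields
        members = [m.strip() for m in members if m.strip()]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has an empty member list")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = set(members)
        provenance[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, provenance=provenance)


def write_table(table: pd.DataFrame, path) -> None:
    """Write a tabular result as TSV with header; floats at 6 significant digits."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory {path.parent} does not exist")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def write_expression(dataset: ExpressionDataset, matrix_path, sheet_path) -> None:
    """Write a dataset in the matrix + sample-sheet dialect read by load_expression."""
    matrix = dataset.values.copy()
    matrix.insert(0, "gene_id", matrix.index)
    write_table(matrix.reset_index(drop=True), matrix_path)
    sheet = dataset.samples.copy()
    if "species" not in sheet.columns:
        sheet.insert(1, "species", dataset.species_label)
    write_table(sheet[["sample_id", "species", "stage", "replicate"]], sheet_path)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    write_table(omap.to_frame(), path)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    path = Path(path)
    lines = []
    for name in collection.names():
        desc = collection.provenance.get(name, "")
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, desc, *members]))
    path.write_text("\n".join(lines) + "\n")
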