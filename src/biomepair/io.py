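"""TSV readers/writers for abundance tables, metadata and distance matrices.

Dialect: tab-separated, UTF-8, lines starting with ``#`` ignored.  Abundance
tables are stored taxa-by-samples with leading lineage columns
(``taxon_id``, ``kingdom``, ``phylum``, ``genus`` and, for species/OTU rank,
``species``) followed by one integer column per sample.  Unknown metadata
values are empty strings on disk and ``None`` in memory.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .core import (
    RANKS,
    AbundanceTable,
    DistanceMatrix,
    ParseError,
    SampleRecord,
    TaxonLineage,
    ValidationError,
)

PathLike = Union[str, Path]

_LINEAGE_COLS = ("taxon_id", "kingdom", "phylum", "genus")


def _read_rows(path: PathLike) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return [
            row
            for row in csv.reader(fh, delimiter="\t")
            if row and not row[0].startswith("#")
        ]


def read_abundance_tsv(path: PathLike, kingdom: str, rank: str = "genus") -> AbundanceTable:
    """Read a taxon-by-sample count table; row/column order is preserved."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    n_lineage = len(_LINEAGE_COLS) + (1 if "species" in header[:6] else 0)
    expected = list(_LINEAGE_COLS) + (["species"] if n_lineage == 5 else [])
    if header[:n_lineage] != expected:
        raise ParseError(
            f"{path}: header must start with {expected}, got {header[:n_lineage]}"
        )
    sample_ids = header[n_lineage:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample IDs in header")
    taxa, counts = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}")
        species = row[4] or None if n_lineage == 5 else None
        try:
            taxa.append(
                TaxonLineage(
                    taxon_id=row[0], kingdom=row[1] or kingdom,
                    phylum=row[2], genus=row[3], species=species,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        vals = []
        for cell in row[n_lineage:]:
            try:
                v = int(cell)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count {cell!r}") from exc
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative count {v}")
            vals.append(v)
        counts.append(vals)
    arr = np.asarray(counts, dtype=float).reshape(len(taxa), len(sample_ids))
    try:
        return AbundanceTable(taxa=taxa, samples=list(sample_ids), counts=arr, rank=rank)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_abundance_tsv(table: AbundanceTable, path: PathLike) -> None:
    with_species = table.rank in ("otu", "species")
    cols = list(_LINEAGE_COLS) + (["species"] if with_species else [])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols + list(table.samples))
        for t, row in zip(table.taxa, table.counts):
            lineage = [t.taxon_id, t.kingdom, t.phylum, t.genus]
            if with_species:
                lineage.append(t.species or "")
            if table.is_relative:
                w.writerow(lineage + [repr(float(v)) for v in row])
            else:
                w.writerow(lineage + [str(int(round(v))) for v in row])


_META_OPTIONAL = ("t_stage", "n_stage", "smoking", "age", "sex")


def read_metadata_tsv(path: PathLike) -> list[SampleRecord]:
    """Read sample metadata; enum fields are case-normalized and validated."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    for req in ("sample_id", "patient_id", "tissue"):
        if req not in header:
            raise ParseError(f"{path}: missing required column {req!r}")
    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        d = dict(zip(header, row))
        try:
            rec = SampleRecord(
                sample_id=d["sample_id"],
                patient_id=d["patient_id"],
                tissue=d["tissue"],
                **{
                    k: (d.get(k) or None)
                    for k in _META_OPTIONAL
                    if d.get(k) not in (None, "")
                },
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        key = (rec.patient_id, rec.tissue)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate (patient_id, tissue) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_metadata_tsv(metadata: Sequence[SampleRecord], path: PathLike) -> None:
    cols = ["sample_id", "patient_id", "tissue", *_META_OPTIONAL]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in metadata:
            vals = [getattr(r, c) for c in cols]
            w.writerow(["" if v is None else v for v in vals])


def write_distance_tsv(dm: DistanceMatrix, path: PathLike) -> None:
    """Square TSV with a header row and a leading ID column."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([""] + list(dm.sample_ids))
        for sid, row in zip(dm.sample_ids, dm.d):
            w.writerow([sid] + [repr(float(v)) for v in row])


def read_distance_tsv(path: PathLike) -> DistanceMatrix:
    rows = _read_rows(path)
    ids = rows[0][1:]
    d = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return DistanceMatrix(sample_ids=ids, d=d)
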