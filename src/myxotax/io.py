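"""Reading and writing the pipeline's file formats.

FASTA goes through Biopython; tabular files (metadata, matrices,
reports) through pandas.  The metadata table is a TSV with the header
``id  strain_key  env_category  country  latitude  longitude  cultured``
and empty fields for missing values.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .core import Alignment, SequenceRecord, ValidationError

METADATA_COLUMNS = [
    "id",
    "strain_key",
    "env_category",
    "country",
    "latitude",
    "longitude",
    "cultured",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (wrapped or single-line) FASTA into (id, residues) pairs."""
    pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate FASTA ids: {dupes}")
    return pairs


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (all rows equal length) into an Alignment."""
    pairs = read_fasta(path)
    return Alignment([i for i, _ in pairs], [r for _, r in pairs])


def write_fasta(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    records = [_BioRecord(Seq(r), id=i, description="") for i, r in pairs]
    SeqIO.write(records, str(path), "fasta")


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sequence metadata TSV; validates the header."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns: {missing}")
    return df


def load_records(
    fasta_path: str | Path, metadata_path: str | Path | None = None
) -> list[SequenceRecord]:
    """Join FASTA residues with the metadata table into SequenceRecords.

    Sequences absent from the metadata get default (unknown) metadata;
    metadata rows without a sequence are an error.
    """
    pairs = read_fasta(fasta_path)
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        df = read_metadata(metadata_path)
        known = {i for i, _ in pairs}
        orphans = sorted(set(df["id"]) - known)
        if orphans:
            raise ValidationError(f"metadata rows without a sequence: {orphans}")
        for row in df.itertuples(index=False):
            meta[row.id] = {
                "strain_key": row.strain_key or row.id,
                "env_category": row.env_category or "The_unknown",
                "country": row.country or "unknown",
                "latitude": _opt_float(row.latitude),
                "longitude": _opt_float(row.longitude),
                "cultured": row.cultured or "unknown",
            }
    return [SequenceRecord(id=i, residues=r, **meta.get(i, {})) for i, r in pairs]


def write_metadata(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "strain_key": rec.strain_key,
                "env_category": rec.env_category,
                "country": rec.country,
                "latitude": "" if rec.latitude is None else rec.latitude,
                "longitude": "" if rec.longitude is None else rec.longitude,
                "cultured": rec.cultured,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
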