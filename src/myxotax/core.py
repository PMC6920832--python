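"""Shared domain types, vocabularies and exceptions.

The package models a community of near-full-length (>=1200 bp) 16S rRNA
gene sequences of myxobacteria (order *Myxococcales*), each carrying
isolation metadata: the strain it came from, one of ten fixed
environmental categories, geography, and whether the organism has been
cultured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: The four nested taxonomic ranks, shallowest (most inclusive) first.
RANKS: tuple[str, ...] = ("suborder", "family", "genus", "species")

#: Closed vocabulary of isolation-environment categories.
ENV_CATEGORIES: tuple[str, ...] = (
    "M_organism",
    "M_sediment",
    "Seawater",
    "Soil",
    "T_sediment",
    "Activated_sludge",
    "T_organism",
    "Freshwater",
    "Human",
    "The_unknown",
)

#: Culturability states.
CULTURABILITY: tuple[str, ...] = ("cultured", "uncultured", "unknown")


class MyxotaxError(Exception):
    """Base class for all package errors."""


class ValidationError(MyxotaxError):
    """Invalid input data or parameters."""


class EmptySequenceError(ValidationError):
    """A sequence with no non-gap residues where residues are required."""


class NonOverlappingPairError(MyxotaxError):
    """Two aligned rows share no column with unambiguous bases in both."""


class SaturationError(MyxotaxError):
    """Substitution saturation: the K2P log argument is non-positive."""


# Residue encoding: A,C,G,T -> 0..3, any IUPAC ambiguity -> 4, gap -> 5.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
# RNA uracil is normalised to thymine.
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3
for _g in "-.":
    _CODE[ord(_g)] = 5

GAP_CODE = 5
AMBIG_CODE = 4


def encode_residues(residues: str) -> np.ndarray:
    """Encode a residue string as int8 codes (ACGT->0..3, ambig->4, gap->5)."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


def normalize_residues(residues: str) -> str:
    """Uppercase and map U->T; leaves gaps and ambiguity codes in place."""
    return residues.upper().replace("U", "T")


@dataclass
class SequenceRecord:
    """One 16S rRNA gene sequence with its isolation metadata.

    ``strain_key`` groups duplicate database deposits of the same strain;
    quality control keeps one representative per key.  ``env_category``
    is one of the ten fixed labels in :data:`ENV_CATEGORIES`.
    """

    id: str
    residues: str
    strain_key: str = ""
    env_category: str = "The_unknown"
    country: str = "unknown"
    latitude: float | None = None
    longitude: float | None = None
    cultured: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be nonempty")
        if not self.residues:
            raise ValidationError(f"{self.id}: residues must be nonempty")
        self.residues = normalize_residues(self.residues)
        if not self.strain_key:
            self.strain_key = self.id
        if self.env_category not in ENV_CATEGORIES:
            raise ValidationError(
                f"{self.id}: unknown environmental category {self.env_category!r}"
            )
        if self.cultured not in CULTURABILITY:
            raise ValidationError(
                f"{self.id}: culturability must be one of {CULTURABILITY}"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.id}: longitude out of range")

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap residues (the length used by QC filters)."""
        codes = encode_residues(self.residues)
        return int(np.count_nonzero(codes != GAP_CODE))


@dataclass
class Alignment:
    """An aligned set of sequences: parallel ids and equal-length rows."""

    ids: list[str]
    rows: list[str]
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows must be parallel")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("alignment ids must be unique")
        if self.rows:
            width = len(self.rows[0])
            for i, row in enumerate(self.rows):
                if len(row) != width:
                    raise ValidationError(
                        f"row {self.ids[i]} has length {len(row)}, expected {width}"
                    )
            self.rows = [normalize_residues(r) for r in self.rows]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encoded(self) -> np.ndarray:
        """(n, width) int8 code matrix; cached after first call."""
        if self._encoded is None:
            self._encoded = (
                np.vstack([encode_residues(r) for r in self.rows])
                if self.rows
                else np.empty((0, 0), dtype=np.int8)
            )
        return self._encoded

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, ids: Sequence[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"ids not in alignment: {missing}")
        return Alignment(list(ids), [self.rows[index[s]] for s in ids])

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))
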