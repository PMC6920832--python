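"""Sequence quality control.

Two filters are applied to every incoming 16S rRNA gene sequence:

* a minimum ungapped length (default 1200 bases, the usual near-full-
  length cutoff for 16S surveys), and
* a maximum ambiguous-base ratio (default strictly below 0.2%, i.e.
  fewer than three ambiguous bases per 1500 — the boundary value 3/1500
  is excluded).

After filtering, duplicate deposits of the same strain are collapsed to
a single representative: the longest high-quality sequence, with ties
broken by the lexicographically smallest id so the result is
deterministic.  Taxonomic pre-screening and chimera removal are assumed
to have happened upstream; this module does not attempt them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    AMBIG_CODE,
    GAP_CODE,
    EmptySequenceError,
    SequenceRecord,
    ValidationError,
    encode_residues,
)

#: Rejection reason codes emitted by :func:`filter_sequences`.
TOO_SHORT = "too_short"
TOO_AMBIGUOUS = "too_ambiguous"


@dataclass(frozen=True)
class QcParams:
    """Quality-control thresholds.

    ``max_ambiguous_ratio`` is an exclusive upper bound: a sequence with
    ambiguous ratio exactly equal to it is rejected.
    """

    min_length: int = 1200
    max_ambiguous_ratio: float = 0.002

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValidationError("min_length must be positive")
        if not 0.0 <= self.max_ambiguous_ratio < 1.0:
            raise ValidationError("max_ambiguous_ratio must be in [0, 1)")


def ambiguous_ratio(record: SequenceRecord) -> float:
    """Fraction of non-gap residues that are not unambiguous A/C/G/T.

    Gaps are excluded from both numerator and denominator, so the ratio
    is identical whether the sequence is supplied aligned or unaligned.
    """
    codes = encode_residues(record.residues)
    nongap = codes != GAP_CODE
    n = int(np.count_nonzero(nongap))
    if n == 0:
        raise EmptySequenceError(f"{record.id}: sequence is all gaps")
    n_ambig = int(np.count_nonzero(codes == AMBIG_CODE))
    return n_ambig / n


def filter_sequences(
    records: Iterable[SequenceRecord], params: QcParams = QcParams()
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Partition records into QC-passing and rejected (with reason codes).

    Length is checked first, so a record failing both filters is
    reported as ``too_short``.  Input order is preserved on both sides.
    """
    kept: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        if rec.ungapped_length < params.min_length:
            rejected.append((rec, TOO_SHORT))
        elif ambiguous_ratio(rec) >= params.max_ambiguous_ratio:
            rejected.append((rec, TOO_AMBIGUOUS))
        else:
            kept.append(rec)
    return kept, rejected


def dedupe_by_strain(records: Iterable[SequenceRecord]) -> list[SequenceRecord]:
    """Keep one representative per strain_key: longest, then smallest id.

    Output follows the input order of each chosen representative.
    """
    records = list(records)
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        cur = best.get(rec.strain_key)
        if cur is None or (
            (rec.ungapped_length, _neg_ord(rec.id))
            > (cur.ungapped_length, _neg_ord(cur.id))
        ):
            best[rec.strain_key] = rec
    chosen = set(id(r) for r in best.values())
    return [r for r in records if id(r) in chosen]


class _neg_ord:
    """Ordering adapter: compares strings in reverse, so that a max over
    (length, _neg_ord(id)) prefers the lexicographically smallest id."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_neg_ord") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_neg_ord") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_ord) and self.s == other.s


def rejection_report(rejected: list[tuple[SequenceRecord, str]]) -> pd.DataFrame:
    """TSV-ready report of rejected ids and reasons."""
    return pd.DataFrame(
        [(rec.id, reason) for rec, reason in rejected], columns=["id", "reason"]
    )


def write_rejection_report(
    path: str | Path, rejected: list[tuple[SequenceRecord, str]]
) -> None:
    rejection_report(rejected).to_csv(path, sep="\t", index=False)
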