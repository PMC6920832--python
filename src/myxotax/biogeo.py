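"""Environmental distributions, abundance, specificity, culturability.

A suborder is *abundant* when it holds at least 0.5% of all sequences
(inclusive), otherwise *rare*.  A taxon is a habitat *specialist* when
it has at least five observations and at least 80% of them come from a
single environmental category (both bounds inclusive); any other taxon
— including those with too few observations — is *cosmopolitan*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ENV_CATEGORIES, RANKS, SequenceRecord, ValidationError
from .delineate import TaxonomyAssignment

ABUNDANT = "abundant"
RARE = "rare"
SPECIALIST = "specialist"
COSMOPOLITAN = "cosmopolitan"


@dataclass(frozen=True)
class AbundanceParams:
    """Sequence-share cutoff separating abundant from rare suborders."""

    cutoff: float = 0.005  # inclusive for abundant

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValidationError("cutoff must be in (0, 1)")


@dataclass(frozen=True)
class SpecificityParams:
    """Habitat-specificity criterion: >= min_obs observations of which
    >= dominance (fraction) fall in one environmental category."""

    min_obs: int = 5
    dominance: float = 0.80  # inclusive
    include_unknown: bool = True  # count The_unknown toward dominance

    def __post_init__(self) -> None:
        if self.min_obs < 1:
            raise ValidationError("min_obs must be >= 1")
        if not 0.0 < self.dominance <= 1.0:
            raise ValidationError("dominance must be in (0, 1]")


def classify_abundance(
    count: int, total: int, params: AbundanceParams = AbundanceParams()
) -> str:
    """'abundant' iff count/total >= cutoff (inclusive)."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError("count must be in [0, total]")
    return ABUNDANT if count / total >= params.cutoff else RARE


def distribution_matrix(
    assignment: TaxonomyAssignment,
    records: Sequence[SequenceRecord],
    rank: str,
) -> pd.DataFrame:
    """Taxon x environment count matrix at one rank.

    Rows are taxon names, columns the ten fixed environmental
    categories (The_unknown is a real column).  Row sums equal the
    taxon sizes in the assignment.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}")
    by_id = {rec.id: rec for rec in records}
    missing = sorted(set(assignment.paths) - set(by_id))
    if missing:
        raise ValidationError(f"assigned ids without records: {missing}")
    partition = assignment.partition(rank)
    rows = {}
    for label in sorted(partition, key=lambda lb: (-len(partition[lb]), min(partition[lb]))):
        counts = dict.fromkeys(ENV_CATEGORIES, 0)
        for seq_id in partition[label]:
            counts[by_id[seq_id].env_category] += 1
        rows[assignment.name_of(label)] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(ENV_CATEGORIES)).fillna(0).astype(int)


def classify_specificity(
    env_counts: Sequence[int] | np.ndarray | dict[str, int],
    params: SpecificityParams = SpecificityParams(),
) -> str:
    """'specialist' iff total obs >= min_obs and max share >= dominance."""
    if isinstance(env_counts, dict):
        counts = np.array(
            [env_counts.get(env, 0) for env in ENV_CATEGORIES], dtype=float
        )
        if not params.include_unknown:
            counts[ENV_CATEGORIES.index("The_unknown")] = 0.0
    else:
        counts = np.asarray(env_counts, dtype=float)
        if not params.include_unknown and len(counts) == len(ENV_CATEGORIES):
            counts = counts.copy()
            counts[ENV_CATEGORIES.index("The_unknown")] = 0.0
    if (counts < 0).any():
        raise ValidationError("environment counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValidationError("taxon has no observations")
    if total >= params.min_obs and counts.max() / total >= params.dominance:
        return SPECIALIST
    return COSMOPOLITAN


def specificity_profile(
    assignment: TaxonomyAssignment,
    records: Sequence[SequenceRecord],
    params: SpecificityParams = SpecificityParams(),
) -> pd.DataFrame:
    """Per-rank fractions of specialist vs cosmopolitan taxa.

    One row per rank with the number of taxa and the two fractions
    (which sum to 1 within each rank).
    """
    rows = []
    for rank in RANKS:
        table = distribution_matrix(assignment, records, rank)
        classes = [
            classify_specificity(row.to_numpy(), params)
            for _, row in table.iterrows()
        ]
        n = len(classes)
        n_spec = sum(c == SPECIALIST for c in classes)
        rows.append(
            {
                "rank": rank,
                "n_taxa": n,
                "specialist_fraction": n_spec / n if n else 0.0,
                "cosmopolitan_fraction": (n - n_spec) / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def culturability_breakdown(
    records: Sequence[SequenceRecord],
    assignment: TaxonomyAssignment | None = None,
) -> tuple[pd.DataFrame, dict[str, int], pd.DataFrame | None]:
    """Culturability shares per environment, global counts, and (when an
    assignment is given) per-suborder culturability counts.

    The per-environment table holds percentages that sum to 100 within
    each environment (up to rounding).
    """
    classes = ("cultured", "uncultured", "unknown")
    env_counts: dict[str, dict[str, int]] = {
        env: dict.fromkeys(classes, 0) for env in ENV_CATEGORIES
    }
    global_counts = dict.fromkeys(classes, 0)
    for rec in records:
        env_counts[rec.env_category][rec.cultured] += 1
        global_counts[rec.cultured] += 1
    rows = []
    for env in ENV_CATEGORIES:
        counts = env_counts[env]
        n = sum(counts.values())
        row = {"env_category": env, "n": n}
        for cls in classes:
            row[f"pct_{cls}"] = 100.0 * counts[cls] / n if n else 0.0
        rows.append(row)
    per_env = pd.DataFrame(rows)

    per_suborder = None
    if assignment is not None:
        by_id = {rec.id: rec for rec in records}
        partition = assignment.partition("suborder")
        sub_rows = []
        for label in sorted(partition, key=lambda lb: (-len(partition[lb]), min(partition[lb]))):
            counts = dict.fromkeys(classes, 0)
            for seq_id in partition[label]:
                counts[by_id[seq_id].cultured] += 1
            sub_rows.append({"suborder": assignment.name_of(label), **counts})
        per_suborder = pd.DataFrame(sub_rows)
    return per_env, global_counts, per_suborder


def abundance_table(
    assignment: TaxonomyAssignment,
    params: AbundanceParams = AbundanceParams(),
) -> pd.DataFrame:
    """Per-suborder sequence counts with abundance classes."""
    partition = assignment.partition("suborder")
    total = sum(len(m) for m in partition.values())
    rows = []
    for label in sorted(partition, key=lambda lb: (-len(partition[lb]), min(partition[lb]))):
        count = len(partition[label])
        rows.append(
            {
                "suborder": assignment.name_of(label),
                "sequences": count,
                "class": classify_abundance(count, total, params),
            }
        )
    return pd.DataFrame(rows)


def abundant_suborders(
    assignment: TaxonomyAssignment,
    params: AbundanceParams = AbundanceParams(),
) -> list[str]:
    table = abundance_table(assignment, params)
    return table.loc[table["class"] == ABUNDANT, "suborder"].tolist()
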