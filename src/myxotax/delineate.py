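"""Nested four-rank taxonomic delineation from pairwise identities.

Sequences are partitioned at four fixed 16S rRNA identity thresholds —
two sequences at or below 97.0% identity are taken as distinct species,
at or below 94.5% as distinct genera, 89.0% as distinct families and
85.0% as distinct suborders.  Complete-linkage (furthest-neighbour)
agglomeration is used because it is the one standard linkage whose
clusters *guarantee* the pairwise statement: every within-cluster pair
has identity strictly greater than the rank threshold.

Clustering is top-down nested: suborders are delineated on the full
matrix, then each suborder is re-clustered at the family threshold, and
so on, which makes the species/genus/family/suborder partitions nested
by construction.

An optional rooted guide tree can refine the partition: any taxon whose
members are not monophyletic is split into its maximal monophyletic
member groups (splitting preserves the identity guarantee; merging
could violate it, so taxa are never merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import RANKS, MyxotaxError, ValidationError
from .distance import DistanceMatrix


@dataclass(frozen=True)
class RankThresholds:
    """Identity cutoffs per rank; a pair at or below the cutoff is split."""

    species: float = 0.970
    genus: float = 0.945
    family: float = 0.890
    suborder: float = 0.850

    def __post_init__(self) -> None:
        if not self.species > self.genus > self.family > self.suborder:
            raise ValidationError("thresholds must decrease with rank depth")
        for t in (self.species, self.genus, self.family, self.suborder):
            if not 0.0 < t < 1.0:
                raise ValidationError("thresholds must lie in (0, 1)")

    def for_rank(self, rank: str) -> float:
        return getattr(self, rank)


def cluster_at_threshold(dm: DistanceMatrix, t: float) -> list[list[str]]:
    """Complete-linkage clusters in which every pair has identity > t.

    Agglomerates greedily: repeatedly merge the two clusters with the
    highest complete-linkage identity (the minimum pairwise identity
    across the two member sets), while that linkage exceeds ``t``
    strictly.  Ties are broken by the smallest member id of the merged
    pair, then by the other cluster's smallest id, so the procedure is
    deterministic and independent of input order.

    Returns clusters as sorted id lists, ordered by smallest member id.
    """
    if dm.metric != "identity":
        raise ValidationError("clustering requires an identity matrix")
    n = len(dm.ids)
    if n == 0:
        return []
    link = dm.values.astype(float).copy()
    np.fill_diagonal(link, -np.inf)
    active = list(range(n))
    members: list[list[str] | None] = [[s] for s in dm.ids]
    minid: list[str | None] = list(dm.ids)

    while len(active) > 1:
        sub = link[np.ix_(active, active)]
        best = sub.max()
        if not best > t:
            break
        cand = np.argwhere(sub == best)
        # tie-break on (smaller min-id, larger min-id) of the candidate pair
        def key(pair: np.ndarray) -> tuple[str, str]:
            a, b = active[pair[0]], active[pair[1]]
            lo, hi = sorted((minid[a], minid[b]))  # type: ignore[type-var]
            return (lo, hi)

        i_sub, j_sub = min(cand, key=key)
        i, j = active[i_sub], active[j_sub]
        if minid[j] < minid[i]:  # type: ignore[operator]
            i, j = j, i
        members[i] = sorted(members[i] + members[j])  # type: ignore[operator]
        link[i, :] = np.minimum(link[i, :], link[j, :])
        link[:, i] = link[i, :]
        link[i, i] = -np.inf
        members[j] = None
        minid[j] = None
        active.remove(j)

    out = [members[a] for a in active]
    return sorted(out, key=lambda c: c[0])  # type: ignore[index]


@dataclass
class TaxonomyAssignment:
    """A nested four-rank partition of sequence ids.

    ``paths`` maps each id to a 4-tuple of integer indices
    (suborder, family, genus, species); a rank label is the prefix of
    the path at that rank's depth, so nesting holds structurally.
    """

    paths: dict[str, tuple[int, int, int, int]]
    names: dict[str, dict[tuple, str]] = field(default_factory=dict)

    def label(self, seq_id: str, rank: str) -> tuple:
        depth = RANKS.index(rank) + 1
        return self.paths[seq_id][:depth]

    def partition(self, rank: str) -> dict[tuple, set[str]]:
        depth = RANKS.index(rank) + 1
        out: dict[tuple, set[str]] = {}
        for seq_id, path in self.paths.items():
            out.setdefault(path[:depth], set()).add(seq_id)
        return out

    def counts(self) -> dict[str, int]:
        """Number of distinct taxa per rank."""
        return {rank: len(self.partition(rank)) for rank in RANKS}

    def name_of(self, label: tuple) -> str:
        rank = RANKS[len(label) - 1]
        return self.names.get(rank, {}).get(label, _default_name(label))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": seq_id,
                **{
                    rank: self.name_of(self.label(seq_id, rank))
                    for rank in RANKS
                },
            }
            for seq_id in sorted(self.paths)
        ]
        return pd.DataFrame(rows, columns=["id", *RANKS])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _default_name(label: tuple) -> str:
    parts = [f"Suborder_{label[0]}"]
    for rank, idx in zip(("Family", "Genus", "Species"), label[1:]):
        parts.append(f"{rank}_{idx}")
    return "_".join(parts)


def nested_delineation(
    dm: DistanceMatrix, thresholds: RankThresholds = RankThresholds()
) -> TaxonomyAssignment:
    """Top-down nested clustering at the four rank thresholds."""
    paths: dict[str, list[int]] = {s: [] for s in dm.ids}
    if len(dm.ids) == 1:
        return TaxonomyAssignment({dm.ids[0]: (1, 1, 1, 1)})

    def descend(sub_dm: DistanceMatrix, rank_i: int) -> None:
        t = thresholds.for_rank(RANKS[rank_i])
        clusters = cluster_at_threshold(sub_dm, t)
        for idx, cluster in enumerate(clusters, start=1):
            for seq_id in cluster:
                paths[seq_id].append(idx)
            if rank_i + 1 < len(RANKS):
                if len(cluster) == 1:
                    paths[cluster[0]].extend([1] * (len(RANKS) - rank_i - 1))
                else:
                    descend(sub_dm.submatrix(cluster), rank_i + 1)

    descend(dm, 0)
    return TaxonomyAssignment({s: tuple(p) for s, p in paths.items()})


# ---------------------------------------------------------------------------
# Tree-guided refinement


def _leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = frozenset({node.taxon.label})
        else:
            sets[node] = frozenset().union(*(sets[c] for c in node.child_nodes()))
    return sets


def _maximal_monophyletic_groups(
    members: set[str],
    tree: dendropy.Tree,
    leaf_sets: dict[dendropy.Node, frozenset[str]],
) -> list[set[str]]:
    """Partition ``members`` into the leaf sets of the maximal clades
    wholly contained in ``members``."""
    groups: list[set[str]] = []

    def walk(node: dendropy.Node) -> None:
        inside = leaf_sets[node] <= members
        if inside:
            groups.append(set(leaf_sets[node]))
            return
        for child in node.child_nodes():
            if leaf_sets[child] & members:
                walk(child)

    walk(tree.seed_node)
    return groups


def refine_with_tree(
    assignment: TaxonomyAssignment, tree: dendropy.Tree
) -> TaxonomyAssignment:
    """Split non-monophyletic taxa by a rooted guide tree.

    Works from the deepest rank (species) upward; each taxon whose
    member set is not exactly the leaf set of a clade is replaced by its
    maximal monophyletic member groups.  Only splits are performed, so
    the within-taxon identity guarantee of the threshold clustering is
    preserved; the nested structure is re-canonicalised afterwards.
    """
    leaf_sets = _leaf_sets(tree)
    tips = leaf_sets[tree.seed_node]
    missing = sorted(set(assignment.paths) - set(tips))
    if missing:
        raise ValidationError(f"tree is missing tips for: {missing}")

    # Extended paths: each rank index becomes (index, group#); group# is
    # refined per rank from deepest to shallowest.
    ext: dict[str, list[tuple]] = {
        s: [(i,) for i in path] for s, path in assignment.paths.items()
    }
    for depth in range(len(RANKS) - 1, -1, -1):
        taxa: dict[tuple, set[str]] = {}
        for seq_id in ext:
            key = tuple(ext[seq_id][: depth + 1])
            taxa.setdefault(key, set()).add(seq_id)
        for key, members in taxa.items():
            groups = _maximal_monophyletic_groups(members, tree, leaf_sets)
            if len(groups) <= 1:
                continue
            groups.sort(key=lambda g: min(g))
            for g_i, group in enumerate(groups):
                for seq_id in group:
                    ext[seq_id][depth] = ext[seq_id][depth] + (g_i,)

    return _canonicalize(ext)


def _canonicalize(ext: dict[str, list[tuple]]) -> TaxonomyAssignment:
    """Renumber extended path components to consecutive ints per parent,
    ordered by each taxon's smallest member id."""
    ids = sorted(ext)
    paths: dict[str, tuple[int, ...]] = {s: () for s in ids}
    for depth in range(len(RANKS)):
        # group children by (parent int path, raw component)
        children: dict[tuple, dict[tuple, str]] = {}
        for s in ids:
            parent = paths[s]
            raw = ext[s][depth]
            smallest = children.setdefault(parent, {})
            if raw not in smallest or s < smallest[raw]:
                smallest[raw] = s
        numbering: dict[tuple, dict[tuple, int]] = {}
        for parent, raw_map in children.items():
            ordered = sorted(raw_map, key=lambda r: raw_map[r])
            numbering[parent] = {raw: i + 1 for i, raw in enumerate(ordered)}
        new_paths = {}
        for s in ids:
            parent = paths[s]
            new_paths[s] = parent + (numbering[parent][ext[s][depth]],)
        paths = new_paths
    return TaxonomyAssignment({s: p for s, p in paths.items()})  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Naming and summary


class AnchorConflictError(MyxotaxError):
    """Anchors assign conflicting names to or across suborders."""


NAME_PATTERN = r"^[A-Za-z_0-9]+(_Family_\d+(_Genus_\d+(_Species_\d+)?)?)?$"


def name_taxa(
    assignment: TaxonomyAssignment, anchors: dict[str, str] | None = None
) -> TaxonomyAssignment:
    """Attach hierarchical names to every taxon.

    Suborders holding an anchored sequence id take the anchor's name
    (e.g. a classical suborder such as *Sorangiineae*); the rest are
    named ``Suborder_N`` in order of decreasing size (ties by smallest
    member id), numbering only the unanchored ones.  Families, genera
    and species are numbered within their parent in the same order,
    yielding names like ``Sorangiineae_Family_2_Genus_5_Species_1``.
    """
    anchors = anchors or {}
    sub_partition = assignment.partition("suborder")
    unknown = sorted(set(anchors) - set(assignment.paths))
    if unknown:
        raise ValidationError(f"anchor ids not in assignment: {unknown}")

    anchor_names: dict[tuple, str] = {}
    for seq_id, name in sorted(anchors.items()):
        label = assignment.label(seq_id, "suborder")
        if label in anchor_names and anchor_names[label] != name:
            raise AnchorConflictError(
                f"suborder {label} anchored as both "
                f"{anchor_names[label]!r} and {name!r}"
            )
        anchor_names[label] = name
    if len(set(anchor_names.values())) != len(anchor_names):
        raise AnchorConflictError("the same anchor name maps to two suborders")

    def order(partition: dict[tuple, set[str]]) -> list[tuple]:
        return sorted(partition, key=lambda lb: (-len(partition[lb]), min(partition[lb])))

    names: dict[str, dict[tuple, str]] = {rank: {} for rank in RANKS}
    counter = 0
    for label in order(sub_partition):
        if label in anchor_names:
            names["suborder"][label] = anchor_names[label]
        else:
            counter += 1
            names["suborder"][label] = f"Suborder_{counter}"

    for depth, (rank, tag) in enumerate(
        zip(("family", "genus", "species"), ("Family", "Genus", "Species")), start=1
    ):
        partition = assignment.partition(rank)
        by_parent: dict[tuple, list[tuple]] = {}
        for label in partition:
            by_parent.setdefault(label[:depth], []).append(label)
        parent_rank = RANKS[depth - 1]
        for parent, labels in by_parent.items():
            sub = {lb: partition[lb] for lb in labels}
            for i, label in enumerate(order(sub), start=1):
                names[rank][label] = f"{names[parent_rank][parent]}_{tag}_{i}"

    return TaxonomyAssignment(dict(assignment.paths), names)


def round_percent(count: int, total: int) -> float:
    """Percentage of total rounded to 2 decimals, half to even."""
    pct = Decimal(count) * 100 / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


TAXON_TABLE_COLUMNS = [
    "abundance",
    "suborder",
    "families",
    "genera",
    "species",
    "sequences",
    "percent",
]


def taxon_table_from_counts(
    rows: pd.DataFrame, abundant_cutoff: float = 0.005
) -> pd.DataFrame:
    """Build the per-suborder summary table from raw per-suborder counts.

    ``rows`` needs columns suborder/families/genera/species/sequences.
    Adds the abundant/rare flag (sequence share >= cutoff is abundant),
    the percentage of all sequences (2 decimals, half-even), and a
    ``Total`` row whose rank columns are column sums.
    """
    required = {"suborder", "families", "genera", "species", "sequences"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"counts table missing columns: {sorted(missing)}")
    total = int(rows["sequences"].sum())
    if total == 0:
        raise ValidationError("no sequences in counts table")
    out = rows.loc[:, ["suborder", "families", "genera", "species", "sequences"]].copy()
    out["percent"] = [round_percent(int(c), total) for c in out["sequences"]]
    out["abundance"] = [
        "Abundant" if c / total >= abundant_cutoff else "Rare"
        for c in out["sequences"]
    ]
    totals = {
        "abundance": "Total",
        "suborder": str(len(out)),
        "families": int(out["families"].sum()),
        "genera": int(out["genera"].sum()),
        "species": int(out["species"].sum()),
        "sequences": total,
        "percent": 100.0,
    }
    out = pd.concat([out, pd.DataFrame([totals])], ignore_index=True)
    return out.loc[:, TAXON_TABLE_COLUMNS]


def summarize_taxonomy(
    assignment: TaxonomyAssignment, abundant_cutoff: float = 0.005
) -> pd.DataFrame:
    """Per-suborder taxon counts, sequence shares and abundance flags."""
    sub_partition = assignment.partition("suborder")
    rows = []
    for label in sorted(sub_partition):
        members = sub_partition[label]
        row = {"suborder": assignment.name_of(label)}
        for rank, col in zip(
            ("family", "genus", "species"), ("families", "genera", "species")
        ):
            depth = RANKS.index(rank) + 1
            row[col] = len({assignment.paths[s][:depth] for s in members})
        row["sequences"] = len(members)
        rows.append(row)
    order = np.argsort([-r["sequences"] for r in rows], kind="stable")
    frame = pd.DataFrame([rows[i] for i in order])
    return taxon_table_from_counts(frame, abundant_cutoff=abundant_cutoff)
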