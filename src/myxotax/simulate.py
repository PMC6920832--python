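"""Synthetic 16S communities with known nested taxonomy.

The generator plants a four-level hierarchy (suborders > families >
genera > species > sequences) by mutating a random root sequence top-
down.  Each edge applies a calibrated number of substitutions at sites
chosen without replacement, excluding sites already mutated on the path
from the root and sites used by sibling edges, so pairwise differences
accumulate almost additively and realized pairwise identities land in
controlled bands:

* within species            [0.985, 1.000]
* between species / genus   [0.950, 0.965]
* between genera / family   [0.905, 0.935]
* between families / subord [0.860, 0.882]
* between suborders         [0.700, 0.840]

Every band is separated from the delineation thresholds
(0.970/0.945/0.890/0.850) by at least 0.005 identity, so threshold
clustering recovers the planted taxonomy exactly.  Realized identities
are audited after generation; a community violating its bands is
regenerated from a derived seed (with these margins that is rare).

Environment labels are planted at one rank (species by default): each
taxon is flagged specialist with a configurable probability; specialist
taxa place >= 90% of their members in one home category while
cosmopolitan taxa draw from the global category weights and are redrawn
if they accidentally satisfy the specificity criterion, so the planted
class always matches what the classifier recovers.

The generator targets identity-band structure, not evolutionary
realism: there is no rate heterogeneity, no indels by default, and no
geographic signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CULTURABILITY,
    ENV_CATEGORIES,
    RANKS,
    Alignment,
    SequenceRecord,
    ValidationError,
)
from .biogeo import SPECIALIST, SpecificityParams, classify_specificity
from .delineate import RankThresholds

_BASES = "ACGT"
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T

#: Global environmental-category weights, matching the published
#: composition of the real 4997-sequence collection (soil-dominated,
#: ~9% marine organisms, ~7% marine sediments, ...).
DEFAULT_ENV_WEIGHTS: dict[str, float] = {
    "Soil": 0.5942,
    "M_organism": 0.0911,
    "M_sediment": 0.0692,
    "Activated_sludge": 0.0680,
    "T_organism": 0.0508,
    "Human": 0.0320,
    "T_sediment": 0.0300,
    "Freshwater": 0.0250,
    "Seawater": 0.0100,
    "The_unknown": 0.0297,
}

#: Global culturability proportions of the real collection
#: (1101 cultured / 3890 uncultured / 6 undetermined of 4997).
DEFAULT_CULTURABILITY: dict[str, float] = {
    "cultured": 1101 / 4997,
    "uncultured": 3890 / 4997,
    "unknown": 6 / 4997,
}

Count = int | tuple[int, int]


@dataclass
class SimSpec:
    """Parameters of a synthetic community.

    Count fields accept a fixed integer or an inclusive (lo, hi) range
    resolved per parent.  ``bands`` maps pair classes to target
    identity intervals; ``kappa`` is the transition/transversion weight
    ratio used when choosing substitution targets.
    """

    suborders: Count = 4
    families_per_suborder: Count = 2
    genera_per_family: Count = 2
    species_per_genus: Count = 2
    sequences_per_species: Count = 7
    length: int = 1400
    kappa: float = 2.0
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "within_species": (0.985, 1.0),
            "between_species": (0.950, 0.965),
            "between_genera": (0.905, 0.935),
            "between_families": (0.860, 0.882),
            "between_suborders": (0.70, 0.84),
        }
    )
    specialist_fraction: float = 0.5
    specificity_rank: str = "species"
    specialist_dominance: float = 0.9
    env_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_WEIGHTS)
    )
    culturability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CULTURABILITY)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValidationError("sequence length must be >= 100")
        if self.kappa <= 0:
            raise ValidationError("kappa must be positive")
        if not 0.0 <= self.specialist_fraction <= 1.0:
            raise ValidationError("specialist_fraction must be in [0, 1]")
        if self.specificity_rank not in RANKS:
            raise ValidationError(f"unknown rank {self.specificity_rank!r}")
        if set(self.bands) != {
            "within_species",
            "between_species",
            "between_genera",
            "between_families",
            "between_suborders",
        }:
            raise ValidationError("bands must cover the five pair classes")
        unknown_env = set(self.env_weights) - set(ENV_CATEGORIES)
        if unknown_env:
            raise ValidationError(f"unknown env categories: {sorted(unknown_env)}")
        if set(self.culturability) - set(CULTURABILITY):
            raise ValidationError("bad culturability classes")
        validate_bands(self.bands)


def validate_bands(
    bands: dict[str, tuple[float, float]],
    thresholds: RankThresholds = RankThresholds(),
    margin: float = 0.005,
) -> None:
    """Bands must be ordered, pairwise disjoint, and clear of every
    threshold by at least ``margin`` identity."""
    order = [
        "between_suborders",
        "between_families",
        "between_genera",
        "between_species",
        "within_species",
    ]
    prev_hi = -1.0
    for name in order:
        lo, hi = bands[name]
        if not 0.0 <= lo < hi <= 1.0:
            raise ValidationError(f"band {name} is not a valid interval")
        if lo <= prev_hi:
            raise ValidationError(f"band {name} overlaps the band below it")
        prev_hi = hi
    cuts = [
        thresholds.suborder,
        thresholds.family,
        thresholds.genus,
        thresholds.species,
    ]
    for name in order:
        lo, hi = bands[name]
        for t in cuts:
            if lo - margin < t < hi + margin:
                raise ValidationError(
                    f"band {name} comes within {margin} of threshold {t}"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated community."""

    paths: dict[str, tuple[int, int, int, int]]  # id -> planted labels
    planted_counts: dict[str, int]  # taxa per rank
    planted_specificity: dict[str, dict]  # taxon key -> class/home env
    band_audit: dict[str, dict]  # pair class -> realized min/max/n
    spec: SimSpec

    def taxon_key(self, path_prefix: tuple) -> str:
        return ".".join(str(i) for i in path_prefix)

    def to_json(self) -> str:
        payload = {
            "paths": {s: list(p) for s, p in self.paths.items()},
            "planted_counts": self.planted_counts,
            "planted_specificity": self.planted_specificity,
            "band_audit": self.band_audit,
            "spec": _spec_dict(self.spec),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _spec_dict(spec: SimSpec) -> dict:
    d = asdict(spec)
    d["bands"] = {k: list(v) for k, v in spec.bands.items()}
    return d


def _resolve(count: Count, rng: np.random.Generator) -> int:
    if isinstance(count, tuple):
        lo, hi = count
        if not 1 <= lo <= hi:
            raise ValidationError(f"bad count range {count}")
        return int(rng.integers(lo, hi + 1))
    if count < 1:
        raise ValidationError("counts must be >= 1")
    return int(count)


def _calibrate(spec: SimSpec) -> tuple[dict[str, int], int]:
    """Substitutions per edge at each level, plus the per-sequence cap.

    Works upward from the tips: given the expected contribution of the
    deeper levels to a pair's difference count, the edge substitution
    count is set so the pair's total difference hits the centre of its
    band.  The worst-case realized interval is then checked against the
    band itself.
    """
    L = spec.length
    ws_lo, ws_hi = spec.bands["within_species"]
    m_max = max(1, math.floor((1.0 - ws_lo) * L / 4))
    if 1.0 - 2.0 * m_max / L < ws_lo or 1.0 - 2.0 / L < ws_lo:
        raise ValidationError(
            f"within_species band infeasible at length {L}: a single"
            " substitution per sequence already leaves the band"
        )
    mean_m = (1 + m_max) / 2.0
    levels = [
        ("between_species", "species"),
        ("between_genera", "genus"),
        ("between_families", "family"),
        ("between_suborders", "suborder"),
    ]
    k: dict[str, int] = {}
    lo_acc, hi_acc, mid_acc = 2.0, 2.0 * m_max, 2.0 * mean_m
    for band_name, level in levels:
        lo, hi = spec.bands[band_name]
        centre = (lo + hi) / 2.0
        edge = round((L * (1.0 - centre) - mid_acc) / 2.0)
        if edge < 1:
            raise ValidationError(
                f"band {band_name} infeasible at length {L}: no room for"
                " substitutions beyond the deeper levels"
            )
        k[level] = int(edge)
        lo_acc += 2 * edge
        hi_acc += 2 * edge
        mid_acc += 2 * edge
        got_lo, got_hi = 1.0 - hi_acc / L, 1.0 - lo_acc / L
        if got_lo < lo or got_hi > hi:
            raise ValidationError(
                f"band {band_name} infeasible: planted identities"
                f" [{got_lo:.4f}, {got_hi:.4f}] leave [{lo}, {hi}]"
            )
    return k, m_max


def _mutate(
    seq: np.ndarray, sites: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    out = seq.copy()
    p_ts = kappa / (kappa + 2.0)
    for s in sites:
        b = int(out[s])
        if rng.random() < p_ts:
            out[s] = _TRANSITION[b]
        else:
            others = [x for x in range(4) if x != b and x != _TRANSITION[b]]
            out[s] = others[int(rng.integers(2))]
    return out


def _pair_class(pa: tuple, pb: tuple) -> str:
    if pa[0] != pb[0]:
        return "between_suborders"
    if pa[1] != pb[1]:
        return "between_families"
    if pa[2] != pb[2]:
        return "between_genera"
    if pa[3] != pb[3]:
        return "between_species"
    return "within_species"


def _audit_bands(
    aln: Alignment, paths: dict[str, tuple], bands: dict[str, tuple[float, float]]
) -> tuple[dict[str, dict], bool]:
    from .distance import identity_matrix

    dm = identity_matrix(aln)
    stats = {
        name: {"min": 1.0, "max": 0.0, "n": 0, "band": list(band), "ok": True}
        for name, band in bands.items()
    }
    n = len(dm.ids)
    path_arr = [paths[s] for s in dm.ids]
    for i in range(n):
        for j in range(i + 1, n):
            cls = _pair_class(path_arr[i], path_arr[j])
            ident = float(dm.values[i, j])
            st = stats[cls]
            st["n"] += 1
            st["min"] = min(st["min"], ident)
            st["max"] = max(st["max"], ident)
    ok = True
    for name, st in stats.items():
        lo, hi = bands[name]
        if st["n"] and not (lo <= st["min"] and st["max"] <= hi):
            st["ok"] = False
            ok = False
    return stats, ok


def _draw_sites(
    pool: np.ndarray, counts: list[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Disjoint site sets of the requested sizes from one pool."""
    need = sum(counts)
    if need > pool.size:
        raise ValidationError(
            f"site budget exhausted: need {need} sites, {pool.size} free"
        )
    perm = rng.permutation(pool)
    out, at = [], 0
    for c in counts:
        out.append(np.sort(perm[at : at + c]))
        at += c
    return out


def _assign_environments(
    members_per_taxon: dict[tuple, list[str]],
    spec: SimSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, dict]]:
    """Plant environments at the specificity rank (with rejection so the
    planted class is exactly what the classifier recovers)."""
    envs = list(spec.env_weights)
    w = np.array([spec.env_weights[e] for e in envs], dtype=float)
    w = w / w.sum()
    params = SpecificityParams()
    env_of: dict[str, str] = {}
    planted: dict[str, dict] = {}
    for taxon in sorted(members_per_taxon):
        members = sorted(members_per_taxon[taxon])
        n = len(members)
        specialist = bool(rng.random() < spec.specialist_fraction)
        key = ".".join(str(i) for i in taxon)
        if specialist:
            home = envs[int(rng.choice(len(envs), p=w))]
            n_home = math.ceil(spec.specialist_dominance * n)
            draws = [home] * n_home + [
                envs[int(rng.choice(len(envs), p=w))] for _ in range(n - n_home)
            ]
            order = rng.permutation(n)
            for idx, m in enumerate(members):
                env_of[m] = draws[order[idx]]
            planted[key] = {"class": "specialist", "home_env": home, "n": n}
        else:
            for _ in range(200):
                draws = [envs[int(i)] for i in rng.choice(len(envs), size=n, p=w)]
                counts = {e: draws.count(e) for e in set(draws)}
                if n < params.min_obs:
                    break
                if classify_specificity(counts, params) != SPECIALIST:
                    break
            else:
                raise ValidationError(
                    "could not draw a cosmopolitan environment profile"
                )
            for m, e in zip(members, draws):
                env_of[m] = e
            planted[key] = {"class": "cosmopolitan", "home_env": None, "n": n}
    return env_of, planted


def generate_community(
    spec: SimSpec, max_attempts: int = 5
) -> tuple[Alignment, list[SequenceRecord], SyntheticTruth]:
    """Generate an aligned community, metadata records, and ground truth.

    Fully reproducible from ``spec.seed``; the realized identity bands
    are audited and generation retries from a derived seed if any pair
    falls outside its band.
    """
    last_audit = None
    for attempt in range(max_attempts):
        rng = np.random.default_rng([spec.seed, attempt])
        aln, records, truth = _generate_once(spec, rng)
        audit, ok = _audit_bands(aln, truth.paths, spec.bands)
        truth.band_audit = audit
        if ok:
            return aln, records, truth
        last_audit = audit
    raise ValidationError(
        f"band audit failed in {max_attempts} attempts: {last_audit}"
    )


def _generate_once(
    spec: SimSpec, rng: np.random.Generator
) -> tuple[Alignment, list[SequenceRecord], SyntheticTruth]:
    L = spec.length
    k_edge, m_max = _calibrate(spec)
    root = rng.integers(0, 4, size=L, dtype=np.int8)
    all_sites = np.arange(L)

    paths: dict[str, tuple[int, int, int, int]] = {}
    seqs: dict[str, np.ndarray] = {}
    serial = 0
    level_names = ("family", "genus", "species")
    counts_spec = (
        spec.families_per_suborder,
        spec.genera_per_family,
        spec.species_per_genus,
    )

    def expand(
        node_seq: np.ndarray,
        path: tuple[int, ...],
        used_mask: np.ndarray,
        level_i: int,
    ) -> None:
        # used_mask is shared by the whole suborder subtree: every edge
        # below one suborder mutates a fresh set of sites, so pairwise
        # differences within a suborder are exactly additive.
        nonlocal serial
        pool = all_sites[~used_mask]
        if level_i == len(level_names):
            n_seq = _resolve(spec.sequences_per_species, rng)
            ms = [int(rng.integers(1, m_max + 1)) for _ in range(n_seq)]
            site_sets = _draw_sites(pool, ms, rng)
            for sites in site_sets:
                used_mask[sites] = True
                serial += 1
                seq_id = f"syn{serial:05d}"
                seqs[seq_id] = _mutate(node_seq, sites, spec.kappa, rng)
                paths[seq_id] = path  # type: ignore[assignment]
            return
        n_children = _resolve(counts_spec[level_i], rng)
        k = k_edge[level_names[level_i]]
        site_sets = _draw_sites(pool, [k] * n_children, rng)
        for sites in site_sets:
            used_mask[sites] = True
        for child_i, sites in enumerate(site_sets, start=1):
            child_seq = _mutate(node_seq, sites, spec.kappa, rng)
            expand(child_seq, path + (child_i,), used_mask, level_i + 1)

    n_suborders = _resolve(spec.suborders, rng)
    sub_sites = _draw_sites(all_sites, [k_edge["suborder"]] * n_suborders, rng)
    for sub_i, sites in enumerate(sub_sites, start=1):
        sub_seq = _mutate(root, sites, spec.kappa, rng)
        mask = np.zeros(L, dtype=bool)
        mask[sites] = True
        expand(sub_seq, (sub_i,), mask, 0)

    ids = sorted(paths)
    aln = Alignment(ids, ["".join(_BASES[b] for b in seqs[s]) for s in ids])

    # environments at the specificity rank
    depth = RANKS.index(spec.specificity_rank) + 1
    members_per_taxon: dict[tuple, list[str]] = {}
    for seq_id, path in paths.items():
        members_per_taxon.setdefault(path[:depth], []).append(seq_id)
    env_of, planted_spec = _assign_environments(members_per_taxon, spec, rng)

    # culturability: global categorical draw
    classes = list(spec.culturability)
    cw = np.array([spec.culturability[c] for c in classes], dtype=float)
    cw = cw / cw.sum()
    cult_draw = rng.choice(len(classes), size=len(ids), p=cw)
    records = [
        SequenceRecord(
            id=seq_id,
            residues=aln.row(seq_id),
            strain_key=seq_id,
            env_category=env_of[seq_id],
            cultured=classes[int(c)],
        )
        for seq_id, c in zip(ids, cult_draw)
    ]

    planted_counts = {
        rank: len({p[: RANKS.index(rank) + 1] for p in paths.values()})
        for rank in RANKS
    }
    truth = SyntheticTruth(
        paths=paths,
        planted_counts=planted_counts,
        planted_specificity=planted_spec,
        band_audit={},
        spec=spec,
    )
    return aln, records, truth


def true_tree_newick(truth: SyntheticTruth) -> str:
    """Newick string of the generation hierarchy (every planted taxon is
    a clade, so tree refinement is a no-op on the truth labels)."""
    children: dict[tuple, set[tuple]] = {(): set()}
    leaves: dict[tuple, list[str]] = {}
    for seq_id, path in truth.paths.items():
        for d in range(1, 5):
            children.setdefault(path[: d - 1], set()).add(path[:d])
        leaves.setdefault(path, []).append(seq_id)

    def render(node: tuple) -> str:
        if len(node) == 4:
            tips = ",".join(f"{s}:0.002" for s in sorted(leaves[node]))
            return f"({tips}):0.02"
        parts = ",".join(render(c) for c in sorted(children[node]))
        return f"({parts}):0.02" if node else f"({parts});"

    return render(())


def write_fixture(
    outdir: str | Path,
    aln: Alignment,
    records: list[SequenceRecord],
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write community.fasta, metadata.tsv, truth.json and tree.nwk."""
    from .io import write_fasta, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "fasta": outdir / "community.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
        "tree": outdir / "tree.nwk",
    }
    write_fasta(files["fasta"], list(zip(aln.ids, aln.rows)))
    write_metadata(files["metadata"], records)
    files["truth"].write_text(truth.to_json())
    files["tree"].write_text(true_tree_newick(truth) + "\n")
    return files
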