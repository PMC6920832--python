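"""Whole-pipeline orchestration: QC -> distances -> delineation ->
biogeography -> rarefaction, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import biogeo, qc, rarefy
from .core import RANKS, ValidationError
from .delineate import (
    RankThresholds,
    name_taxa,
    nested_delineation,
    refine_with_tree,
    summarize_taxonomy,
)
from .distance import identity_matrix, k2p_matrix, long_format
from .io import load_records, write_fasta, write_metadata
from .qc import QcParams
from .simulate import SimSpec


@dataclass
class RunConfig:
    """Inputs, parameters and output location of one pipeline run."""

    fasta: Path
    metadata: Path | None = None
    tree: Path | None = None
    anchors: Path | None = None
    outdir: Path = Path("myxotax_out")
    qc_params: QcParams = field(default_factory=QcParams)
    thresholds: RankThresholds = field(default_factory=RankThresholds)
    abundance: biogeo.AbundanceParams = field(default_factory=biogeo.AbundanceParams)
    specificity: biogeo.SpecificityParams = field(
        default_factory=biogeo.SpecificityParams
    )
    rarefaction_points: int = 20
    k2p_max_distance: float | None = None
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def read_anchors(path: Path) -> dict[str, str]:
    """Anchors TSV: columns id, suborder_name."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["id", "suborder_name"]:
        raise ValidationError("anchors file needs columns: id, suborder_name")
    return dict(zip(df["id"], df["suborder_name"]))


def new_taxa_delta(
    totals: dict[str, int], reference_counts: dict[str, int]
) -> dict[str, int]:
    """Newly delineated taxa per rank: totals minus previously known."""
    out = {}
    for rank in RANKS:
        diff = totals[rank] - reference_counts[rank]
        if diff < 0:
            raise ValidationError(
                f"reference count exceeds total at rank {rank}:"
                f" {reference_counts[rank]} > {totals[rank]}"
            )
        out[rank] = diff
    return out


def _depth_grid(n_total: int, points: int) -> list[int]:
    if n_total <= points:
        return list(range(1, n_total + 1))
    step = n_total / points
    grid = sorted({1, n_total, *(max(1, round(step * i)) for i in range(1, points))})
    return grid


def run_all(config: RunConfig) -> dict:
    """Run every stage in order and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) with
    every parameter, input checksum and per-stage record counts.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest: dict = {
        "parameters": {
            "qc": vars(config.qc_params).copy(),
            "thresholds": vars(config.thresholds).copy(),
            "abundance": vars(config.abundance).copy(),
            "specificity": vars(config.specificity).copy(),
            "rarefaction_points": config.rarefaction_points,
            "seed": config.seed,
            "linkage": "complete",
            "threshold_scale": "raw identity (pairwise deletion)",
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("fasta", "metadata", "tree", "anchors"):
        path = getattr(config, name)
        if path is not None:
            path = Path(path)
            if not path.exists():
                raise ValidationError(f"input {name} not found: {path}")
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = {
            "elapsed_s": round(time.monotonic() - t0, 3),
            **counts,
        }

    # --- QC -------------------------------------------------------------
    records = load_records(config.fasta, config.metadata)
    kept, rejected = qc.filter_sequences(records, config.qc_params)
    kept = qc.dedupe_by_strain(kept)
    qc.write_rejection_report(outdir / "qc_rejected.tsv", rejected)
    write_fasta(outdir / "qc_passed.fasta", [(r.id, r.residues) for r in kept])
    write_metadata(outdir / "qc_passed_metadata.tsv", kept)
    stage("qc", input=len(records), kept=len(kept), rejected=len(rejected))
    if len(kept) < 2:
        raise ValidationError("fewer than two sequences survived QC")

    # --- distances ------------------------------------------------------
    from .core import Alignment

    aln = Alignment([r.id for r in kept], [r.residues for r in kept])
    ident = identity_matrix(aln)
    k2p = k2p_matrix(aln, max_distance=config.k2p_max_distance)
    ident.write_tsv(outdir / "identity_matrix.tsv")
    k2p.write_tsv(outdir / "k2p_matrix.tsv")
    long_format(ident, k2p).to_csv(outdir / "pairwise_long.tsv", sep="\t", index=False)
    stage("distances", pairs=len(aln) * (len(aln) - 1) // 2)

    # --- delineation ----------------------------------------------------
    assignment = nested_delineation(ident, config.thresholds)
    if config.tree is not None:
        tree = dendropy.Tree.get(path=str(config.tree), schema="newick")
        assignment = refine_with_tree(assignment, tree)
    anchors = read_anchors(Path(config.anchors)) if config.anchors else None
    assignment = name_taxa(assignment, anchors)
    assignment.write_tsv(outdir / "assignment.tsv")
    table = summarize_taxonomy(assignment, abundant_cutoff=config.abundance.cutoff)
    table.to_csv(outdir / "taxon_table.tsv", sep="\t", index=False)
    stage("delineation", **assignment.counts())

    # --- biogeography ---------------------------------------------------
    for rank in RANKS:
        biogeo.distribution_matrix(assignment, kept, rank).to_csv(
            outdir / f"distribution_{rank}.tsv", sep="\t", index_label="taxon"
        )
    profile = biogeo.specificity_profile(assignment, kept, config.specificity)
    profile.to_csv(outdir / "specificity_profile.tsv", sep="\t", index=False)
    per_env, global_counts, per_suborder = biogeo.culturability_breakdown(
        kept, assignment
    )
    per_env.to_csv(outdir / "culturability_env.tsv", sep="\t", index=False)
    if per_suborder is not None:
        per_suborder.to_csv(
            outdir / "culturability_suborder.tsv", sep="\t", index=False
        )
    stage("biogeography", **{f"n_{k}": v for k, v in global_counts.items()})

    # --- rarefaction ----------------------------------------------------
    abundant = biogeo.abundant_suborders(assignment, config.abundance)
    curves = []
    coverages = []
    for by, labels in (("suborder", abundant), ("env", None)):
        groups = rarefy.group_abundances(assignment, kept, by=by, labels=labels)
        if not groups:
            continue
        n_max = max(sum(v) for v in groups.values())
        grid = _depth_grid(n_max, config.rarefaction_points)
        curve = rarefy.curve_family(groups, grid)
        curve.insert(0, "grouping", by)
        curves.append(curve)
        cov = rarefy.coverage_table(groups)
        cov.insert(0, "grouping", by)
        coverages.append(cov)
    pd.concat(curves, ignore_index=True).to_csv(
        outdir / "rarefaction_curves.tsv", sep="\t", index=False
    )
    pd.concat(coverages, ignore_index=True).to_csv(
        outdir / "coverage.tsv", sep="\t", index=False
    )
    stage("rarefaction", groups=sum(len(c) for c in coverages))

    manifest["totals"] = assignment.counts()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def parse_config_file(path: str | Path) -> dict[str, str]:
    """Parse a simple ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def simspec_from_config(options: dict[str, str]) -> SimSpec:
    """Build a SimSpec from config-file options (unknown keys rejected)."""
    kwargs: dict = {}
    int_fields = {
        "suborders",
        "families_per_suborder",
        "genera_per_family",
        "species_per_genus",
        "sequences_per_species",
        "length",
        "seed",
    }
    float_fields = {"kappa", "specialist_fraction", "specialist_dominance"}
    for key, value in options.items():
        if key in int_fields:
            value = value.strip()
            if "-" in value and not value.startswith("-"):  # 'lo-hi' range
                lo, hi = value.split("-", 1)
                kwargs[key] = (int(lo), int(hi))
            else:
                kwargs[key] = int(value)
        elif key in float_fields:
            kwargs[key] = float(value)
        elif key == "specificity_rank":
            kwargs[key] = value
        else:
            raise ValidationError(f"unknown simulation option {key!r}")
    return SimSpec(**kwargs)
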