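"""End-to-end pipeline: simulate -> classify -> rarefy -> stats -> traits -> converge.

One config drives the whole run; every intermediate table is written as TSV
with a commented header carrying the governing parameters, and a JSON
manifest records parameters, per-stage row counts and output checksums.
Runs are idempotent: the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_samples, collapse_rare_pseudo_clades
from .community import rarefy, relative_abundance, restrict_to_main_clades
from .convergence import convergence_distances, group_centroids
from .simulate import (
    ScenarioParams,
    build_design,
    simulate_hit_tables,
    simulate_trait_matrix,
    write_annotations,
    write_hit_table,
)
from .stats import bray_curtis, pcoa, permanova, permdisp
from .traits import pca_profiles, permanova_on_profiles, project_traits

DEFAULT_CONFIG: dict = {
    "design": {
        "n_sites": 5,
        "n_inocula": 5,
        "n_replicates": 4,
        "n_timepoints": 3,
        "missing_slots": [["grassland", "desert", "T3", "r1"]],
        "survey_counts": 4,
    },
    "scenario": {
        "scenario": "climate",
        "reads_per_sample": 300,
        "ambiguity_rate": 0.3,
        "decoy_fraction": 0.2,
    },
    "parameters": {
        "min_identity": 98.0,
        "max_evalue": 1e-20,
        "min_pseudo_hits": 10,
        "depth": 50,
        "n_perm": 999,
        "n_axes": 2,
        "seed": 1,
        "grassland_site": "grassland",
        "permdisp_groups": ["site", "type"],
    },
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (user or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        cfg[section].update(values or {})
    return cfg


def validate_config(cfg: dict) -> None:
    p = cfg["parameters"]
    if p["depth"] < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {p['depth']}")
    if p["min_identity"] <= 0 or p["max_evalue"] <= 0:
        raise ValueError("filter thresholds must be positive")
    if p["min_pseudo_hits"] < 1 or p["n_perm"] < 1 or p["n_axes"] < 1:
        raise ValueError("min_pseudo_hits, n_perm and n_axes must be >= 1")
    if cfg["scenario"]["reads_per_sample"] < 1:
        raise ValueError("reads_per_sample must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, cfg: dict, index: bool = True) -> None:
    seed = cfg["parameters"]["seed"]
    with open(path, "w") as fh:
        fh.write(f"# microclade {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute every stage in order and return the run manifest."""
    cfg = merge_config(config)
    validate_config(cfg)
    p = cfg["parameters"]
    seed = int(p["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": cfg,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts

    # --- simulate ---------------------------------------------------------
    d = cfg["design"]
    design = build_design(
        n_sites=d["n_sites"],
        n_inocula=d["n_inocula"],
        n_replicates=d["n_replicates"],
        n_timepoints=d["n_timepoints"],
        missing_slots=[tuple(s) for s in d.get("missing_slots", [])],
        survey_counts=d.get("survey_counts", 4),
    )
    timepoint = design.timepoints[-1]
    params = ScenarioParams(seed=seed, **cfg["scenario"])
    tables, truth, database = simulate_hit_tables(design, params, timepoint)
    metadata = design.metadata(timepoint)
    traits = simulate_trait_matrix(seed=seed)
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    for sample_id, hits in tables.items():
        write_hit_table(hits, hits_dir / f"{sample_id}.tsv")
    write_annotations(database, out / "annotations.tsv")
    _write_tsv(metadata, out / "metadata.tsv", cfg)
    _write_tsv(traits, out / "trait_matrix.tsv", cfg)
    record(
        "simulate",
        n_samples=len(tables),
        reads_per_sample=params.reads_per_sample,
        total_reads=int(truth.shape[0]),
        n_decoy_reads=int(truth["decoy"].sum()),
    )

    # --- classify ---------------------------------------------------------
    counts, diagnostics = classify_samples(
        tables,
        annotations=database,
        min_identity=p["min_identity"],
        max_evalue=p["max_evalue"],
    )
    collapsed = collapse_rare_pseudo_clades(counts, min_hits=p["min_pseudo_hits"])
    _write_tsv(collapsed, out / "clade_counts.tsv", cfg)
    _write_tsv(diagnostics, out / "classification_diagnostics.tsv", cfg)
    n_assigned = int(diagnostics["n_assigned"].sum())
    n_discarded = int(diagnostics["n_discarded"].sum())
    if n_assigned + n_discarded != int(truth.shape[0]):
        raise RuntimeError("classification bookkeeping lost reads")
    record(
        "classify",
        n_assigned=n_assigned,
        n_discarded=n_discarded,
        n_labels=int(collapsed.shape[1]),
    )

    # --- rarefy + relative abundance -------------------------------------
    rarefied, drop_report = rarefy(collapsed, depth=p["depth"], seed=seed)
    _write_tsv(rarefied, out / "rarefied_counts.tsv", cfg)
    _write_tsv(drop_report, out / "rarefaction_drops.tsv", cfg)
    abundance = relative_abundance(rarefied)
    _write_tsv(abundance, out / "clade_relative_abundance.tsv", cfg)
    if len(rarefied) + len(drop_report) != len(collapsed):
        raise RuntimeError("rarefaction bookkeeping lost samples")
    record("rarefy", n_kept=len(rarefied), n_dropped=len(drop_report), depth=p["depth"])

    # --- clade ordination + PERMANOVA / PERMDISP --------------------------
    md = metadata.loc[abundance.index]
    dm = bray_curtis(abundance)
    ordination = pcoa(dm)
    _write_tsv(ordination.coordinates, out / "pcoa_coordinates.tsv", cfg)
    transplant_ids = md.index[md["type"] == "transplant"]
    perm = permanova(
        bray_curtis(abundance.loc[transplant_ids]),
        md,
        terms=("site", "inoculum", "site:inoculum"),
        n_permutations=p["n_perm"],
        seed=seed,
    )
    _write_tsv(perm.to_frame(), out / "permanova_clades.tsv", cfg)
    groups = md[list(p["permdisp_groups"])].astype(str).agg("/".join, axis=1)
    disp = permdisp(dm, groups, n_permutations=p["n_perm"], seed=seed)
    disp_summary = pd.DataFrame(
        [
            {
                "F": disp.f,
                "p": disp.p,
                "Df": disp.df,
                "SS": disp.ss_between,
                "R2": disp.r2,
            }
        ]
    )
    _write_tsv(disp_summary, out / "permdisp_clades.tsv", cfg, index=False)
    record("stats", n_samples=len(dm), n_permutations=p["n_perm"])

    # --- trait projection -------------------------------------------------
    main_abund, main_drops = restrict_to_main_clades(abundance)
    profiles = project_traits(main_abund, traits)
    _write_tsv(profiles, out / "trait_profiles.tsv", cfg)
    pca = pca_profiles(profiles)
    _write_tsv(pca.scores, out / "trait_pca_scores.tsv", cfg)
    _write_tsv(pca.loadings, out / "trait_pca_loadings.tsv", cfg)
    md_traits = md.loc[profiles.index]
    perm_traits = permanova_on_profiles(
        profiles.loc[profiles.index.intersection(transplant_ids)],
        md_traits,
        n_permutations=p["n_perm"],
        seed=seed,
    )
    _write_tsv(perm_traits.to_frame(), out / "permanova_traits.tsv", cfg)
    record("traits", n_samples=len(profiles), n_dropped=len(main_drops))

    # --- convergence ------------------------------------------------------
    centroids = group_centroids(
        ordination.coordinates, md, group_keys=("site", "type"), n_axes=p["n_axes"]
    )
    _write_tsv(centroids.reset_index(), out / "centroids.tsv", cfg, index=False)
    summary = convergence_distances(centroids, grassland_label=p["grassland_site"])
    (out / "convergence.json").write_text(json.dumps(summary.to_dict(), indent=2))
    record("converge", n_centroids=len(centroids), n_axes=p["n_axes"])

    manifest["results"] = {
        "permanova_clades": {
            t.name: {"Df": t.df, "SS": t.ss, "R2": t.r2, "F": t.f, "p": t.p}
            for t in perm.terms
        },
        "permanova_traits": {
            t.name: {"Df": t.df, "SS": t.ss, "R2": t.r2, "F": t.f, "p": t.p}
            for t in perm_traits.terms
        },
        "permdisp_clades": {"F": disp.f, "p": disp.p, "Df": disp.df, "R2": disp.r2},
        "convergence": summary.to_dict(),
    }
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_default_config(path) -> None:
    Path(path).write_text(yaml.safe_dump(DEFAULT_CONFIG, sort_keys=False))
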