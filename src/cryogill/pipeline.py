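"""End-to-end orchestration: simulate -> build matrix -> score -> select
-> tissue-specificity -> enrichment -> clustering, from one config.

Every stage writes its output under the run directory in the pipeline's
declared file formats, so a run can be re-entered at any stage; the
manifest records every parameter, output file and checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import gene_heatmap_transform, species_profile_transform
from .dataio import write_annotation_tsv, write_expression_tsv, write_species_config
from .diffexp import differential_expression, shortlist
from .errors import ValidationError
from .ortholog import build_ortholog_table, write_ortholog_table
from .simulate import (
    SimulationParams,
    identity_membership,
    simulate_annotations,
    simulate_cross_species,
    simulate_tissue_panel,
)
from .tissue import hypergeometric_enrichment, select_tissue_specific

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds in one place.

    Defaults are the published analysis settings: 1-TPM reference filter,
    fold-change 1.5 for the consistency score, CS >= 36 and q < 0.05 for
    candidate selection, top decile + fold 10 for tissue specificity,
    TPM 1000 heatmap floor, CS >= 42 for the species profile.
    """

    seed: int
    outdir: str = "cryogill_run"
    # synthetic cross-species dataset
    sim: dict = field(default_factory=dict)
    # tissue panel + annotations
    panel: dict = field(default_factory=dict)
    # thresholds
    min_tpm: float = 1.0
    fc_threshold: float = 1.5
    pseudocount: float = 0.1
    cs_min: int = 36
    q_max: float = 0.05
    top_fraction: float = 0.10
    fc_min: float = 10.0
    heatmap_min_tpm: float = 1000.0
    profile_cs_min: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(doc) - known
        if bad:
            raise ValidationError(f"{path}: unknown config keys {sorted(bad)}")
        if "seed" not in doc:
            raise ValidationError(f"{path}: a seed is required")
        return cls(**doc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = SimulationParams(seed=config.seed, **config.sim)
    if config.cs_min > params.n_antarctic * params.n_other:
        raise ValidationError(
            f"unsatisfiable threshold: cs_min={config.cs_min} exceeds "
            f"{params.n_antarctic}x{params.n_other} comparisons"
        )
    for name in (
        "min_tpm", "fc_threshold", "pseudocount", "cs_min", "q_max",
        "top_fraction", "fc_min", "heatmap_min_tpm", "profile_cs_min",
    ):
        log.info("threshold %s = %s", name, getattr(config, name))
    prov = f"cryogill {__version__} seed={config.seed}"
    stages: dict[str, list[str]] = {}

    def emit(stage: str, *paths: Path) -> None:
        stages[stage] = [str(p.relative_to(out)) for p in paths]

    # 1. simulate
    matrices, sp_config, truth = simulate_cross_species(params)
    written = []
    for sp, mat in matrices.items():
        p = out / f"expr_{sp}.tsv"
        write_expression_tsv(p, mat, provenance=prov)
        written.append(p)
    cfg_path = out / "species_config.yaml"
    write_species_config(cfg_path, sp_config)
    truth_path = out / "truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    emit("simulate", *written, cfg_path, truth_path)

    # 2. build matrix
    table = build_ortholog_table(matrices, identity_membership(matrices), sp_config)
    table_path = out / "ortholog_table.tsv"
    write_ortholog_table(table_path, table, provenance=prov)
    emit("build_matrix", table_path)

    # 3. score + 4. select
    deg = differential_expression(
        table,
        fc_threshold=config.fc_threshold,
        pseudocount=config.pseudocount,
        cs_min=config.cs_min,
        q_max=config.q_max,
    )
    deg_path = out / "deg_table.tsv"
    with open(deg_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {prov}\n")
        deg.to_csv(fh, sep="\t", index_label="ortholog_id")
    emit("score", deg_path)
    short_path = out / "candidates.tsv"
    with open(short_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {prov}\n")
        shortlist(deg).to_csv(fh, sep="\t", index_label="ortholog_id")
    emit("select", short_path)

    # 5. tissue specificity
    panel, panel_truth = simulate_tissue_panel(seed=config.seed, **config.panel)
    target = panel.tissues[0]
    specific = select_tissue_specific(
        panel,
        target,
        top_fraction=config.top_fraction,
        fc_min=config.fc_min,
        pseudocount=config.pseudocount,
    )
    spec_path = out / "tissue_specific.tsv"
    pd.Series(specific, name="gene_id").to_csv(spec_path, sep="\t", index=False)
    emit("tissue_spec", spec_path)

    # 6. enrichment
    annotation, _ = simulate_annotations(
        panel.gene_ids,
        target_set=list(panel_truth.tissue_specific),
        seed=config.seed,
    )
    ann_path = out / "annotation.tsv"
    write_annotation_tsv(ann_path, annotation, provenance=prov)
    enrich = hypergeometric_enrichment(specific, panel.gene_ids, annotation)
    enrich_path = out / "enrichment.tsv"
    with open(enrich_path, "w", encoding="utf-8") as fh:
        fh.write(f"# {prov}\n")
        enrich.to_csv(fh, sep="\t")
    emit("enrich", ann_path, enrich_path)

    # 7. clustering
    heat, gene_tree = gene_heatmap_transform(panel, min_max_tpm=config.heatmap_min_tpm)
    heat_path = out / "heatmap_matrix.tsv"
    heat.values.to_csv(heat_path, sep="\t", index_label="gene_id")
    gene_tree_path = out / "gene_dendrogram.nwk"
    gene_tree_path.write_text(gene_tree.to_newick() + "\n")
    prof, sp_tree = species_profile_transform(table, deg, cs_min=config.profile_cs_min)
    prof_path = out / "species_profile.tsv"
    prof.values.to_csv(prof_path, sep="\t", index_label="ortholog_id")
    sp_tree_path = out / "species_dendrogram.nwk"
    sp_tree_path.write_text(sp_tree.to_newick() + "\n")
    emit("cluster", heat_path, gene_tree_path, prof_path, sp_tree_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": stages,
        "checksums": {
            rel: _sha256(out / rel) for outs in stages.values() for rel in outs
        },
        "status": "ok",
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
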