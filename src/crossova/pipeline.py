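"""End-to-end orchestration: simulate (or load), QC, ortholog harmonization,
cell-type similarity, regulon statistics, pathway activity and marker
partitioning, driven by one validated configuration with explicit seeding
and a run manifest of checksums and timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import io as cio
from . import markers as cmarkers
from . import orthologs as corth
from . import pathways as cpath
from . import qc as cqc
from . import regulons as creg
from . import similarity as csim
from . import synthetic as csyn
from .exceptions import ConfigurationError

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "STAGES"]

STAGES = ["simulate", "qc", "orthologs", "similarity", "regulons", "pathways", "markers"]


class SpeciesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species_id: str
    n_cells: int = Field(ge=1)
    cell_type_proportions: dict[str, float]
    library_size_mean: float = 5000.0
    species_effect_sd: float = 0.3


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: list[SpeciesBlock]
    n_genes: int = Field(default=1000, ge=50)
    n_regulons: int = 8
    n_pathways: int = 10
    frac_one2one: float = 0.9
    marker_lfc: float = 2.0
    regulon_activity_lfc: float = 1.0
    pathway_effect: float = 2.0
    species_specific_programs: dict[str, list[str]] = Field(default_factory=dict)


class InputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tenx_dirs: dict[str, str]
    cell_meta: dict[str, str]
    ortholog_table: str
    pathways_gmt: str
    regulons_gmt: str | None = None


class QCBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_genes: int = Field(default=200, ge=0)
    max_mito: float = Field(default=0.10, ge=0)
    min_cells_per_gene: int = Field(default=3, ge=0)
    mito_prefix: str = "MT-"


class RegulonBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_frac: float = 0.05
    csi_min: float = 0.8
    k: int = 4
    aucell_min: float = 0.1
    rssz_min: float = 1.0


class PathwayBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = Field(default=5000, ge=1)


class MarkerBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    min_lfc: float = 0.25


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    reference_species: str | None = None
    species_order: list[str] | None = None
    simulate: SimulateBlock | None = None
    inputs: InputBlock | None = None
    qc: QCBlock = Field(default_factory=QCBlock)
    hvg_n_top: int = 2000
    regulons: RegulonBlock = Field(default_factory=RegulonBlock)
    pathways: PathwayBlock = Field(default_factory=PathwayBlock)
    markers: MarkerBlock = Field(default_factory=MarkerBlock)

    def check(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError("config needs exactly one of 'simulate' or 'inputs'")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg.check()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path, skip: list[str] | None = None) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    Each stage logs its parameters and record counts, writes its outputs
    under ``outdir/<stage>/`` and registers their checksums.  A failing
    stage leaves a FAILED marker naming it and re-raises.
    """
    config.check()
    skip = skip or []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "versions": _versions(),
    }
    state: dict = {}
    current = "setup"
    try:
        for stage in STAGES:
            current = stage
            if stage in skip:
                manifest["stages"][stage] = {"skipped": True}
                continue
            t0 = time.time()
            stage_dir = outdir / stage
            stage_dir.mkdir(exist_ok=True)
            outputs = _STAGE_FUNCS[stage](config, state, stage_dir)
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                **state.pop("_log", {}),
            }
            print(f"[{stage}] done in {manifest['stages'][stage]['seconds']}s: "
                  f"{len(outputs)} output file(s)")
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    cio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _versions() -> dict:
    import anndata
    import scipy
    import sklearn

    from . import __version__

    return {
        "crossova": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "anndata": anndata.__version__,
        "sklearn": sklearn.__version__,
    }


# --- stages ----------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, state: dict, outdir: Path):
    outputs = []
    if cfg.simulate is not None:
        sim = cfg.simulate
        configs = [
            csyn.SpeciesConfig(
                s.species_id, s.n_cells, s.cell_type_proportions,
                s.library_size_mean, s.species_effect_sd,
            )
            for s in sim.species
        ]
        ds = csyn.generate_dataset(
            configs,
            n_genes=sim.n_genes,
            n_regulons=sim.n_regulons,
            n_pathways=sim.n_pathways,
            seed=cfg.seed,
            frac_one2one=sim.frac_one2one,
            marker_lfc=sim.marker_lfc,
            regulon_activity_lfc=sim.regulon_activity_lfc,
            pathway_effect=sim.pathway_effect,
            species_specific_programs=sim.species_specific_programs or None,
        )
        state["adatas"] = ds.adatas
        state["ortholog_table"] = ds.ortholog_table
        state["pathways"] = ds.pathways
        state["regulon_sets"] = ds.ground_truth.regulon_sets()
        state["ground_truth"] = ds.ground_truth
        for sp_id, adata in ds.adatas.items():
            d = outdir / sp_id
            cio.write_tenx(adata, d)
            cio.write_cell_meta(adata.obs[["species", "replicate", "cell_type"]], d / "cell_meta.tsv")
            outputs += [d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", d / "cell_meta.tsv"]
        cio.write_ortholog_tsv(ds.ortholog_table, outdir / "orthologs.tsv")
        cio.write_gmt(ds.pathways, outdir / "pathways.gmt")
        cio.write_gmt(state["regulon_sets"], outdir / "regulons.gmt")
        outputs += [outdir / "orthologs.tsv", outdir / "pathways.gmt", outdir / "regulons.gmt"]
    else:
        inp = cfg.inputs
        adatas = {}
        for sp_id, d in inp.tenx_dirs.items():
            adata = cio.read_tenx(d)
            meta = cio.read_cell_meta(inp.cell_meta[sp_id])
            adata.obs = adata.obs.join(meta)
            adatas[sp_id] = adata
        state["adatas"] = adatas
        state["ortholog_table"] = cio.read_ortholog_tsv(inp.ortholog_table)
        state["pathways"] = cio.read_gmt(inp.pathways_gmt)
        state["regulon_sets"] = cio.read_gmt(inp.regulons_gmt) if inp.regulons_gmt else {}
    state["_log"] = {"n_species": len(state["adatas"])}
    return outputs


def _stage_qc(cfg: PipelineConfig, state: dict, outdir: Path):
    filtered = {}
    reports = []
    for sp_id, adata in state["adatas"].items():
        f = cqc.filter_cells_genes(
            adata,
            min_genes=cfg.qc.min_genes,
            max_mito=cfg.qc.max_mito,
            min_cells_per_gene=cfg.qc.min_cells_per_gene,
            mito_prefix=cfg.qc.mito_prefix,
        )
        filtered[sp_id] = cqc.normalize_log(f)
        reports.append({"species": sp_id, **f.uns["qc_report"]})
    state["normalized"] = filtered
    report = pd.DataFrame(reports)
    report.to_csv(outdir / "qc_report.csv", index=False)
    state["_log"] = {
        "cells_out": int(sum(a.n_obs for a in filtered.values())),
    }
    return [outdir / "qc_report.csv"]


def _stage_orthologs(cfg: PipelineConfig, state: dict, outdir: Path):
    species = list(state["normalized"])
    table = corth.filter_one2one(state["ortholog_table"], species)
    data = corth.harmonize_datasets(state["normalized"], table)
    state["multi"] = data
    pd.Series(data.genes).to_csv(outdir / "shared_genes.txt", index=False, header=False)
    state["_log"] = {"n_shared_genes": len(data.genes), "n_dropped": len(data.dropped_genes)}
    return [outdir / "shared_genes.txt"]


def _stage_similarity(cfg: PipelineConfig, state: dict, outdir: Path):
    data = state["multi"]
    hvgs = csim.voting_hvgs(data, n_top=min(cfg.hvg_n_top, len(data.genes)))
    auroc = csim.neighbor_voting_auroc(data, hvgs=hvgs)
    state["auroc"] = auroc
    flat = auroc.copy()
    flat.index = ["|".join(i) for i in auroc.index]
    flat.columns = ["|".join(c) for c in auroc.columns]
    flat.to_csv(outdir / "auroc_matrix.csv")
    renamed = auroc.copy()
    renamed.index.names = ["species_a", "cell_type_a"]
    renamed.columns.names = ["species_b", "cell_type_b"]
    long = renamed.stack([0, 1], future_stack=True).rename("auroc").reset_index()
    long.dropna().to_csv(outdir / "auroc_long.tsv", sep="\t", index=False)
    spearman = csim.crossspecies_spearman(data, n_top=min(cfg.hvg_n_top, len(data.genes)))
    spearman.to_csv(outdir / "spearman.csv", index=False)
    outputs = [outdir / "auroc_matrix.csv", outdir / "auroc_long.tsv", outdir / "spearman.csv"]
    order = cfg.species_order or list(state["normalized"])
    neighbors = csim.neighbor_species_scores(auroc, order)
    neighbors.to_csv(outdir / "neighbor_species_auroc.csv", index=False)
    outputs.append(outdir / "neighbor_species_auroc.csv")
    state["_log"] = {"n_voting_genes": len(hvgs)}
    return outputs


def _reference_species(cfg: PipelineConfig, state: dict) -> str:
    if cfg.reference_species and cfg.reference_species in state["normalized"]:
        return cfg.reference_species
    return next(iter(state["normalized"]))


def _stage_regulons(cfg: PipelineConfig, state: dict, outdir: Path):
    regulon_sets = state.get("regulon_sets") or {}
    if not regulon_sets:
        state["_log"] = {"n_regulons": 0}
        (outdir / "NO_REGULONS").write_text("no regulon sets supplied\n")
        return [outdir / "NO_REGULONS"]
    ref = _reference_species(cfg, state)
    data = state["multi"].per_species(ref)
    activity = creg.aucell_score(data, regulon_sets, top_frac=cfg.regulons.top_frac)
    rss = creg.compute_rss(
        activity, data.obs["cell_type"],
        aucell_min=cfg.regulons.aucell_min, rssz_min=cfg.regulons.rssz_min,
    )
    csi = creg.compute_csi(activity)
    modules = creg.detect_modules(csi, k=cfg.regulons.k, csi_min=cfg.regulons.csi_min)
    state["activity"], state["csi"], state["modules"] = activity, csi, modules
    activity.to_csv(outdir / "activity.csv")
    rss.to_csv(outdir / "rss.csv", index=False)
    csi.to_csv(outdir / "csi.csv")
    modules.as_series().rename_axis("regulon").to_csv(outdir / "modules.tsv", sep="\t")
    tfs = sorted(regulon_sets)
    targets = sorted({g for genes in regulon_sets.values() for g in genes} - set(tfs))
    im = creg.infer_importance(data, tfs, targets, estimator="correlation", seed=cfg.seed)
    im.to_csv(outdir / "importance.csv", index=False)
    state["_log"] = {"n_regulons": len(regulon_sets), "reference_species": ref}
    return [outdir / "activity.csv", outdir / "rss.csv", outdir / "csi.csv",
            outdir / "modules.tsv", outdir / "importance.csv"]


def _stage_pathways(cfg: PipelineConfig, state: dict, outdir: Path):
    ref = _reference_species(cfg, state)
    outputs = []
    frames = []
    for sp_id, data in state["multi"].adata.obs.groupby("species", observed=True).groups.items():
        sub = state["multi"].per_species(sp_id)
        res = cpath.permutation_test(
            sub, sub.obs["cell_type"], state["pathways"],
            n_perm=cfg.pathways.n_perm, seed=cfg.seed + 17,
        )
        res.insert(0, "species", sp_id)
        frames.append(res)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "pathway_activity.csv", index=False)
    outputs.append(outdir / "pathway_activity.csv")
    state["pathway_table"] = table

    # cross-species effect sizes on per-cell mean pathway expression in one
    # focal cell type (granulosa when present)
    multi = state["multi"].adata
    types = multi.obs["cell_type"].unique()
    focal = "granulosa" if "granulosa" in set(types) else sorted(types)[0]
    rows = []
    species = list(state["normalized"])
    for name, genes in state["pathways"].items():
        present = [g for g in genes if g in set(multi.var_names)]
        if not present:
            continue
        per_cell = {}
        for sp_id in species:
            sub = multi[(multi.obs["species"] == sp_id) & (multi.obs["cell_type"] == focal)]
            if sub.n_obs < 2:
                continue
            x = sub[:, present].X
            x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
            per_cell[sp_id] = x.mean(axis=1)
        for i, s1 in enumerate(species):
            for s2 in species[i + 1:]:
                if s1 in per_cell and s2 in per_cell:
                    try:
                        d = cpath.cohens_d(per_cell[s1], per_cell[s2])
                    except ConfigurationError:
                        continue
                    rows.append({"pathway": name, "cell_type": focal,
                                 "species_a": s1, "species_b": s2, "cohens_d": d})
    pd.DataFrame(rows).to_csv(outdir / "cohens_d.csv", index=False)
    outputs.append(outdir / "cohens_d.csv")
    state["_log"] = {"n_pathways": len(state["pathways"]), "focal_cell_type": focal}
    return outputs


def _stage_markers(cfg: PipelineConfig, state: dict, outdir: Path):
    outputs = []
    per_species_markers: dict[str, dict[str, list[str]]] = {}
    for sp_id, data in state["normalized"].items():
        tables = cmarkers.find_all_markers(
            data, data.obs["cell_type"], alpha=cfg.markers.alpha, min_lfc=cfg.markers.min_lfc
        )
        per_species_markers[sp_id] = cmarkers.marker_lists(tables)
        combined = pd.concat(tables.values(), ignore_index=True)
        path = outdir / f"markers_{sp_id}.csv"
        combined[combined["is_marker"]].to_csv(path, index=False)
        outputs.append(path)
    species = list(state["normalized"])
    table = corth.filter_one2one(state["ortholog_table"], species)
    partition = cmarkers.partition_markers(per_species_markers, table, species)
    state["partition"] = partition
    cio.write_json(partition.to_dict(), outdir / "marker_partition.json")
    outputs.append(outdir / "marker_partition.json")
    state["_log"] = {
        "n_conserved": int(sum(len(v) for v in partition.conserved.values())),
    }
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "orthologs": _stage_orthologs,
    "similarity": _stage_similarity,
    "regulons": _stage_regulons,
    "pathways": _stage_pathways,
    "markers": _stage_markers,
}
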