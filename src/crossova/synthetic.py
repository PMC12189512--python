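"""Multi-species single-cell count simulator with planted ground truth.

The generator emulates the statistical structure of a cross-species ovary
atlas: several species share a conserved expression program per cell type
(endothelial, granulosa, theca, immune, ...), counts are negative binomial
with a per-cell log-normal library size, a fraction of genes are
mitochondrial ("MT-" symbols) and a designated low-quality cell subset has
its mitochondrial means boosted so QC filters have true positives.
Transcription-factor regulons are planted as target sets driven by a latent
per-cell Gamma activity that is high in designated cell types, and pathway
effects multiply the means of pathway member genes in designated
(cell type, species) pairs.  Everything planted is recorded in a
:class:`GroundTruth` so downstream statistics can be scored against it.

Counts are drawn from a Gamma-Poisson mixture, i.e. NB with variance
``mu + dispersion * mu**2``.  The log-mean of gene ``g`` in cell ``c`` of
species ``s`` decomposes as::

    log mu = baseline(g) + species_shift(s, g) + marker_effect(type(c), g)
             + log regulon_multiplier(c, g) + log pathway_effect(...)
             + log library_factor(c)

Marker effects are natural-log fold changes, so the expected mean ratio of a
planted marker between its cell type and the rest is exactly ``exp(lfc)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import ConfigurationError

__all__ = [
    "SpeciesConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_dataset",
    "generate_ortholog_table",
]

DEFAULT_CELL_TYPES = (
    "endothelial",
    "granulosa",
    "theca",
    "immune",
    "smooth-muscle",
    "epithelial",
)


@dataclass
class SpeciesConfig:
    """Per-species simulation settings.

    Parameters
    ----------
    species_id
        Unique species label; also prefixes that species' gene ids.
    n_cells
        Number of cells to simulate (>= 1).
    cell_type_proportions
        Mapping cell type -> fraction; must sum to 1 within 1e-9.
    library_size_mean
        Expected total counts per cell.
    species_effect_sd
        SD of the per-gene species shift on the natural-log scale.
    """

    species_id: str
    n_cells: int
    cell_type_proportions: dict[str, float]
    library_size_mean: float = 5000.0
    species_effect_sd: float = 0.3

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError(f"{self.species_id}: n_cells must be >= 1")
        total = float(sum(self.cell_type_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"{self.species_id}: cell_type_proportions sum to {total!r}, not 1"
            )
        if self.library_size_mean <= 0:
            raise ConfigurationError(f"{self.species_id}: library_size_mean must be > 0")
        if self.species_effect_sd < 0:
            raise ConfigurationError(f"{self.species_id}: species_effect_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by reference gene symbols."""

    conserved_markers: dict[str, list[str]] = field(default_factory=dict)
    species_specific_markers: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    marker_genes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    regulons: dict[str, dict] = field(default_factory=dict)
    pathway_genes: dict[str, list[str]] = field(default_factory=dict)
    pathway_effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str, str, str]] = field(default_factory=list)
    low_quality_cells: dict[str, list[str]] = field(default_factory=dict)

    def regulon_sets(self) -> dict[str, list[str]]:
        """Regulons as plain TF -> target-list gene sets (TF included)."""
        return {tf: [tf, *info["targets"]] for tf, info in self.regulons.items()}


@dataclass
class SyntheticDataset:
    """Simulated multi-species dataset plus its generating truth."""

    adatas: dict[str, ad.AnnData]
    ortholog_table: pd.DataFrame
    pathways: dict[str, list[str]]
    ground_truth: GroundTruth
    seed: int
    ref_genes: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.adatas)


def _species_gene(species: str, ref: str) -> str:
    return f"{species}_{ref}"


def generate_dataset(
    configs: list[SpeciesConfig],
    n_genes: int = 1000,
    n_regulons: int = 8,
    n_pathways: int = 10,
    seed: int = 0,
    *,
    dispersion: float = 0.3,
    mito_gene_frac: float = 0.05,
    n_conserved_markers: int = 20,
    marker_lfc: float = 2.0,
    species_specific_programs: dict[str, list[str]] | None = None,
    n_specific_markers: int = 8,
    specific_marker_lfc: float = 2.0,
    regulon_n_targets: int = 15,
    regulon_activity_lfc: float = 1.0,
    regulon_noise_shape: float = 4.0,
    pathway_size: int = 10,
    pathway_effect: float = 2.0,
    frac_affected_pathways: float = 0.5,
    library_size_sd: float = 0.3,
    low_quality_frac: float = 0.05,
    mito_boost: float = 8.0,
    frac_one2one: float = 0.9,
    n_replicates: int = 2,
) -> SyntheticDataset:
    """Simulate per-species count matrices with planted structure.

    ``n_regulons`` regulons are assigned to cell types round-robin; the
    targets of a regulon are co-activated by a latent Gamma multiplier whose
    mean is ``exp(regulon_activity_lfc)`` in the regulon's cell type and 1
    elsewhere.  ``frac_affected_pathways`` of the pathways get a
    ``pathway_effect``-fold mean shift in one designated cell type (all
    species), in addition to any shifts implied by overlapping genes.
    ``species_specific_programs`` maps species -> cell types that receive an
    extra private marker set (``n_specific_markers`` genes at
    ``specific_marker_lfc``); these genes stay unperturbed in every other
    species, which is what the conserved/species-specific marker partition
    is tested against.
    """
    if n_genes < 50:
        raise ConfigurationError("n_genes must be >= 50")
    ids = [c.species_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate species ids in configs: {ids}")
    for cfg in configs:
        cfg.validate()
    vocab = list(configs[0].cell_type_proportions)
    for cfg in configs[1:]:
        if list(cfg.cell_type_proportions) != vocab:
            raise ConfigurationError(
                "all species configs must share the same cell-type vocabulary"
            )
    species_specific_programs = species_specific_programs or {}
    for sp_id, types in species_specific_programs.items():
        if sp_id not in ids:
            raise ConfigurationError(f"species_specific_programs names unknown species {sp_id!r}")
        for t in types:
            if t not in vocab:
                raise ConfigurationError(f"species_specific_programs names unknown cell type {t!r}")

    rng = np.random.default_rng(seed)
    truth = GroundTruth()

    # --- gene universe: mitochondrial genes first, then nuclear genes ------
    n_mito = int(round(mito_gene_frac * n_genes))
    width = len(str(n_genes))
    ref_genes = [f"MT-G{i + 1:0{width}d}" for i in range(n_mito)] + [
        f"G{i + 1:0{width}d}" for i in range(n_mito, n_genes)
    ]
    nuclear = np.arange(n_mito, n_genes)

    # pools: markers, regulon genes and pathway genes are drawn from disjoint
    # nuclear pools so each planted signal is attributable to one mechanism.
    perm = rng.permutation(nuclear)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        if cursor + n > len(perm):
            raise ConfigurationError(
                f"n_genes={n_genes} too small for the requested planted structure"
            )
        out = perm[cursor : cursor + n]
        cursor += n
        return out

    marker_idx: dict[str, np.ndarray] = {t: take(n_conserved_markers) for t in vocab}
    for t, idx in marker_idx.items():
        truth.conserved_markers[t] = [ref_genes[i] for i in sorted(idx)]
    specific_idx: dict[tuple[str, str], np.ndarray] = {}
    for sp_id, types in species_specific_programs.items():
        for t in types:
            idx = take(n_specific_markers)
            specific_idx[(sp_id, t)] = idx
            truth.species_specific_markers[(sp_id, t)] = [ref_genes[i] for i in sorted(idx)]

    tf_idx = take(n_regulons)
    regulon_targets: dict[str, np.ndarray] = {}
    regulon_type: dict[str, str] = {}
    for r in range(n_regulons):
        tf = ref_genes[tf_idx[r]]
        targets = take(regulon_n_targets)
        active_type = vocab[r % len(vocab)]
        regulon_targets[tf] = targets
        regulon_type[tf] = active_type
        truth.regulons[tf] = {
            "targets": [ref_genes[i] for i in targets],
            "active_types": [active_type],
            "activity_lfc": regulon_activity_lfc,
        }

    # pathway genes may overlap across pathways (sampled with replacement
    # across sets) from their own pool
    pathway_pool = take(max(pathway_size * max(n_pathways, 1) // 2, pathway_size)) if n_pathways else np.array([], int)
    pathways: dict[str, list[str]] = {}
    pathway_idx: dict[str, np.ndarray] = {}
    n_affected = int(round(frac_affected_pathways * n_pathways))
    for p in range(n_pathways):
        name = f"PATHWAY_{p + 1:02d}"
        idx = rng.choice(pathway_pool, size=min(pathway_size, len(pathway_pool)), replace=False)
        pathway_idx[name] = idx
        pathways[name] = [ref_genes[i] for i in sorted(idx)]
        truth.pathway_genes[name] = pathways[name]
    affected = list(pathways)[:n_affected]
    for j, name in enumerate(affected):
        target_type = vocab[j % len(vocab)]
        for sp_id in ids:
            truth.pathway_effects[(name, target_type, sp_id)] = pathway_effect

    # --- shared baseline and simulation per species ------------------------
    baseline = rng.normal(0.0, 1.0, size=n_genes)
    # marker-program genes sit at a common baseline so every cell type's
    # planted program claims the same expected library share; otherwise the
    # random baseline draw gives each type a different total-count boost and
    # depth normalization turns that into spurious cross-type fold changes
    # on unrelated genes
    for idx in marker_idx.values():
        baseline[idx] = 0.0
    for idx in specific_idx.values():
        baseline[idx] = 0.0
    adatas: dict[str, ad.AnnData] = {}
    for cfg in configs:
        sp_id = cfg.species_id
        species_shift = rng.normal(0.0, cfg.species_effect_sd, size=n_genes)

        # per-cell-type log-mean profiles
        type_log_mu = {}
        for t in vocab:
            lm = baseline + species_shift
            lm = lm.copy()
            lm[marker_idx[t]] += marker_lfc
            if (sp_id, t) in specific_idx:
                lm[specific_idx[(sp_id, t)]] += specific_marker_lfc
            type_log_mu[t] = lm

        props = np.array([cfg.cell_type_proportions[t] for t in vocab])
        counts_per_type = _apportion(cfg.n_cells, props)
        cell_types = np.repeat(np.arange(len(vocab)), counts_per_type)
        rng.shuffle(cell_types)

        mu = np.exp(np.stack([type_log_mu[vocab[t]] for t in cell_types]))

        # regulon latent activity: Gamma noise of mean 1, scaled up in the
        # regulon's active cell type
        for tf, targets in regulon_targets.items():
            active = cell_types == vocab.index(regulon_type[tf])
            act = rng.gamma(regulon_noise_shape, 1.0 / regulon_noise_shape, size=cfg.n_cells)
            act = act * np.where(active, np.exp(regulon_activity_lfc), 1.0)
            cols = np.concatenate(([tf_idx[list(regulon_targets).index(tf)]], targets))
            mu[:, cols] *= act[:, None]

        for (name, t, sp_eff), eff in truth.pathway_effects.items():
            if sp_eff != sp_id:
                continue
            rows = cell_types == vocab.index(t)
            mu[np.ix_(rows, pathway_idx[name])] *= eff

        # low-quality subset: boosted mitochondrial means -> high mito fraction
        n_lowq = int(round(low_quality_frac * cfg.n_cells))
        lowq = rng.choice(cfg.n_cells, size=n_lowq, replace=False)
        if n_mito:
            mu[np.ix_(lowq, np.arange(n_mito))] *= mito_boost

        # library size: per-cell log-normal factor; means scaled so a typical
        # cell totals library_size_mean
        lib = cfg.library_size_mean * rng.lognormal(
            -0.5 * library_size_sd**2, library_size_sd, size=cfg.n_cells
        )
        base_total = np.exp(baseline + species_shift).sum()
        mu *= (lib / base_total)[:, None]

        lam = rng.gamma(1.0 / dispersion, dispersion * mu) if dispersion > 0 else mu
        counts = rng.poisson(lam).astype(np.int64)

        barcodes = [f"{sp_id}-C{i + 1:05d}" for i in range(cfg.n_cells)]
        obs = pd.DataFrame(
            {
                "species": sp_id,
                "replicate": [f"r{rng.integers(1, n_replicates + 1)}" for _ in range(cfg.n_cells)],
                "cell_type": [vocab[t] for t in cell_types],
                "is_low_quality": np.isin(np.arange(cfg.n_cells), lowq),
            },
            index=pd.Index(barcodes, name="barcode"),
        )
        var = pd.DataFrame(
            {"symbol": ref_genes, "ref_gene": ref_genes},
            index=pd.Index([_species_gene(sp_id, g) for g in ref_genes], name="gene_id"),
        )
        adatas[sp_id] = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
        truth.low_quality_cells[sp_id] = [barcodes[i] for i in sorted(lowq)]
        for t in vocab:
            planted = list(truth.conserved_markers[t])
            if (sp_id, t) in truth.species_specific_markers:
                planted += truth.species_specific_markers[(sp_id, t)]
            truth.marker_genes[(t, sp_id)] = planted

    dataset = SyntheticDataset(
        adatas=adatas,
        ortholog_table=pd.DataFrame(),
        pathways=pathways,
        ground_truth=truth,
        seed=seed,
        ref_genes=ref_genes,
    )
    dataset.ortholog_table = generate_ortholog_table(dataset, frac_one2one, seed=seed + 1)
    truth.ortholog_pairs = list(dataset.ortholog_table.itertuples(index=False, name=None))
    return dataset


def generate_ortholog_table(
    dataset: SyntheticDataset, frac_one2one: float, seed: int = 0
) -> pd.DataFrame:
    """Build an ortholog table over the dataset's reference genes.

    Exactly ``round(frac_one2one * n_genes)`` reference genes are annotated
    ``one2one_ortholog`` in every species; the rest get ``one2many`` or
    ``none`` independently per species.  Genes carrying planted structure
    (markers, regulons, pathways) are placed in the one-to-one set first so
    the planted truth survives ortholog harmonization.
    """
    if not (0 < frac_one2one <= 1):
        raise ConfigurationError("frac_one2one must be in (0, 1]")
    ref_genes = dataset.ref_genes
    if not ref_genes or not dataset.adatas:
        return pd.DataFrame(columns=["ref_gene", "species", "species_gene", "homology_type"])
    rng = np.random.default_rng(seed)
    n_one = int(round(frac_one2one * len(ref_genes)))

    truth = dataset.ground_truth
    planted: set[str] = set()
    for genes in truth.conserved_markers.values():
        planted.update(genes)
    for genes in truth.species_specific_markers.values():
        planted.update(genes)
    for tf, info in truth.regulons.items():
        planted.add(tf)
        planted.update(info["targets"])
    for genes in truth.pathway_genes.values():
        planted.update(genes)
    planted &= set(ref_genes)

    others = [g for g in ref_genes if g not in planted]
    rng.shuffle(others)
    ordered = sorted(planted) + others
    one2one = set(ordered[:n_one]) if n_one >= len(planted) else set(sorted(planted)[:n_one])

    rows = []
    for sp_id in dataset.species:
        for g in ref_genes:
            if g in one2one:
                htype = "one2one_ortholog"
            else:
                htype = "one2many" if rng.random() < 0.5 else "none"
            rows.append((g, sp_id, _species_gene(sp_id, g), htype))
    return pd.DataFrame(rows, columns=["ref_gene", "species", "species_gene", "homology_type"])


def _apportion(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n cells to proportions (sums to n)."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def null_configs(
    species_ids: list[str],
    n_cells: int,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES[:4],
) -> list[SpeciesConfig]:
    """Convenience: equal-proportion configs with no species shift."""
    props = {t: 1.0 / len(cell_types) for t in cell_types}
    # make proportions sum to exactly 1 despite float division
    props[cell_types[-1]] = 1.0 - sum(props[t] for t in cell_types[:-1])
    return [
        SpeciesConfig(s, n_cells, dict(props), species_effect_sd=0.0) for s in species_ids
    ]
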