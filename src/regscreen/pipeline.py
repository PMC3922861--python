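"""End-to-end orchestration: expression matrix in, ranked candidates out.

Stages: differential-induction calls -> fold-change profiles -> fuzzy
c-means clustering -> reference-cluster extraction -> functional-class
enrichment -> genomic co-regulation scan -> production-rate correlation ->
evidence integration -> candidate ranking. Every output file carries a
provenance header (package version, config hash, seed) and re-parses through
the package's own readers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rsio
from .candidates import (
    DEFAULT_BREADTH_MIN,
    DEFAULT_MIN_CRITERIA,
    build_evidence,
    select_candidates,
)
from .cluster import (
    FuzzyCMeans,
    assign_clusters,
    fold_change_profiles,
    reference_clusters,
    standardize,
)
from .correlation import DEFAULT_CORR_THRESHOLD, production_correlation
from .data import ExpressionDataset, RateSeries
from .diffexpr import (
    DEFAULT_LFC_CUT,
    DEFAULT_P_CUT,
    call_differential,
    fit_contrasts,
    induction_breadth,
)
from .enrichment import annotation_classes, enrich_classes
from .genome import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_MEMBERS,
    DEFAULT_MIN_RUN,
    DEFAULT_WINDOW,
    annotate_neighbors,
    find_adjacent_patches,
    find_coregulated_regions,
    order_genes,
    region_gene_ids,
    regions_to_frame,
)
from .simulate import (
    CAZY_CLASS,
    REGULATOR_CLASS,
    TRANSPORTER_CLASS,
    SimulationConfig,
    SyntheticDataset,
    simulate_experiment,
)

__version__ = "0.1.0"

_INPUT_KEYS = {
    "expression", "design", "genome", "annotations", "reference_genes",
    "rates", "chemostat_expression", "proteome",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Either ``inputs`` maps every input name to a path, or ``simulate`` gives
    :class:`SimulationConfig` keyword arguments and the study is generated
    in-place. Unknown keys are rejected.
    """

    outdir: str = "regscreen_out"
    inputs: dict[str, str] | None = None
    simulate: dict | None = None
    p_cut: float = DEFAULT_P_CUT
    lfc_cut: float = DEFAULT_LFC_CUT
    n_clusters: int = 6
    m: float = 1.25
    cluster_tol: float = 1e-5
    cluster_max_iter: int = 300
    cluster_restarts: int = 3
    alpha: float = 0.5
    reference_coverage: float = 0.9
    window: int = DEFAULT_WINDOW
    min_members: int = DEFAULT_MIN_MEMBERS
    max_gap: int = DEFAULT_MAX_GAP
    min_run: int = DEFAULT_MIN_RUN
    corr_threshold: float = DEFAULT_CORR_THRESHOLD
    corr_method: str = "pearson"
    breadth_min: int = DEFAULT_BREADTH_MIN
    min_criteria: int = DEFAULT_MIN_CRITERIA
    require_regulatory_class: bool = True
    weights: dict[str, float] | None = None
    regulatory_classes: list[str] = field(
        default_factory=lambda: [REGULATOR_CLASS]
    )
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config needs exactly one of 'inputs' or 'simulate'")
        if self.inputs is not None:
            missing = _INPUT_KEYS - set(self.inputs)
            if missing:
                raise ValueError(f"missing input paths: {sorted(missing)}")
        if self.p_cut <= 0 or self.lfc_cut <= 0:
            raise ValueError("p_cut and lfc_cut must be positive")
        if self.corr_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown corr_method {self.corr_method!r}")

    def config_hash(self) -> str:
        # outdir is excluded: the same analysis written to two directories
        # yields byte-identical files
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory results of a full run (mirrors the written outputs)."""

    contrasts: object
    call_summary: pd.DataFrame
    breadth: pd.Series
    profiles: pd.DataFrame
    model: FuzzyCMeans
    assignment: object
    flagged_clusters: list[int]
    co_clustered: list[str]
    enrichment: pd.DataFrame
    regions: list
    patches: list
    correlations: pd.DataFrame
    evidence: pd.DataFrame
    candidates: pd.DataFrame
    run_log: dict
    output_paths: dict[str, Path]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", config.seed)
        dataset = simulate_experiment(SimulationConfig(**sim_kwargs))
        rsio.write_dataset(dataset, outdir / "inputs")
        return dataset
    paths = config.inputs
    data = rsio.read_dataset(paths["expression"], paths["design"])
    genome_path = Path(paths["genome"])
    if genome_path.suffix.lower() == ".bed":
        loci = rsio.read_bed(genome_path)
    else:
        loci = rsio.read_gff3(genome_path)
    return SyntheticDataset(
        expression=data,
        loci=loci,
        annotations=rsio.read_annotations(paths["annotations"]),
        reference_genes=rsio.read_gene_list(paths["reference_genes"]),
        chemostat=rsio.read_rates(paths["rates"], paths["chemostat_expression"]),
        proteome_flags=rsio.read_proteome_flags(paths["proteome"]),
        truth=None,
        config=None,
    )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the full output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"regscreen {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.seed}",
    ]
    dataset = _load_inputs(config, outdir)
    data: ExpressionDataset = dataset.expression
    universe = list(data.gene_ids)

    # 1. differential induction
    contrasts = fit_contrasts(data)
    call_summary = call_differential(contrasts, config.p_cut, config.lfc_cut)
    breadth = induction_breadth(contrasts)

    # 2. clustering of standardized fold-change profiles
    profiles = fold_change_profiles(contrasts)
    std = standardize(profiles)
    model = FuzzyCMeans(
        n_clusters=config.n_clusters,
        m=config.m,
        tol=config.cluster_tol,
        max_iter=config.cluster_max_iter,
        n_init=config.cluster_restarts,
        random_state=config.seed,
    ).fit(std.matrix.to_numpy())
    assignment = assign_clusters(model, std.matrix.index, config.alpha)

    # 3. reference clusters and co-clustered genes
    flagged, co_clustered = reference_clusters(
        assignment, dataset.reference_genes, config.reference_coverage
    )
    refs_present = [
        g for g in dataset.reference_genes if g in assignment.table.index
    ]
    cluster_members = sorted(set(co_clustered) | set(refs_present))

    # 4. functional-class enrichment within the reference clusters
    classes = annotation_classes(dataset.annotations)
    enrichment = enrich_classes(cluster_members, classes, universe)

    # 5. genomic co-regulation scan
    loci = order_genes(dataset.loci)
    regions = find_coregulated_regions(
        loci, assignment, config.window, config.min_members, config.max_gap
    )
    patches = find_adjacent_patches(loci, assignment, config.min_run)

    # 6. production-rate correlation
    correlations = production_correlation(
        dataset.chemostat, config.corr_threshold, config.corr_method
    )

    # 7. evidence and candidates
    reg_class_genes = {
        g
        for label in config.regulatory_classes
        for g in classes.get(label, set())
    }
    roles = pd.Series("other", index=pd.Index(universe, name="gene_id"), dtype=object)
    for label, genes in classes.items():
        role = {CAZY_CLASS: "CAZy", TRANSPORTER_CLASS: "transporter"}.get(label)
        if role is None:
            role = "regulator" if label in config.regulatory_classes else None
        if role:
            roles[roles.index.isin(genes)] = role
    neighbor_report = annotate_neighbors(
        regions + patches, sorted(reg_class_genes), roles, loci
    )
    evidence = build_evidence(
        universe=universe,
        breadth=breadth,
        co_clustered=co_clustered,
        corr=correlations,
        region_gene_ids=region_gene_ids(regions) | region_gene_ids(patches),
        neighbor_report=neighbor_report,
        regulatory_class_genes=reg_class_genes,
        proteome_flags=dataset.proteome_flags,
        breadth_min=config.breadth_min,
    )
    candidates = select_candidates(
        evidence,
        min_criteria=config.min_criteria,
        require_regulatory_class=config.require_regulatory_class,
        weights=config.weights,
    )

    # analogue of the intermediate shortlist: regulatory-class genes either
    # co-clustered with the references or induced on most substrates
    co_or_induced = int(
        (
            evidence["regulatory_class"]
            & (evidence["crit_co_clustered"] | evidence["crit_induction"])
        ).sum()
    )
    run_log = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": {
            "p_cut": config.p_cut,
            "lfc_cut": config.lfc_cut,
            "n_clusters": config.n_clusters,
            "fuzzifier_m": config.m,
            "alpha": config.alpha,
            "window": config.window,
            "min_members": config.min_members,
            "max_gap": config.max_gap,
            "min_run": config.min_run,
            "corr_threshold": config.corr_threshold,
            "breadth_min": config.breadth_min,
            "min_criteria": config.min_criteria,
        },
        "counts": {
            "genes": len(universe),
            "flagged_clusters": flagged,
            "co_clustered": len(co_clustered),
            "regions": len(regions),
            "adjacent_patches": len(patches),
            "correlation_pass": int(correlations["passed"].sum()),
            "regulatory_class_genes": len(reg_class_genes),
            "regulatory_co_clustered_or_induced": co_or_induced,
            "selected_candidates": int(candidates["selected"].sum()),
        },
    }

    paths: dict[str, Path] = {}

    def save(name, frame, index=True):
        paths[name] = outdir / f"{name}.tsv"
        rsio.write_with_header(frame, paths[name], header, index=index)

    save("contrasts", contrasts.table, index=False)
    save("call_summary", call_summary, index=False)
    save("fold_change_matrix", profiles)  # heatmap export
    save("clusters", assignment.table)
    save(
        "centroids",
        pd.DataFrame(model.cluster_centers_, columns=std.matrix.columns).rename_axis("cluster"),
    )
    save("enrichment", enrichment, index=False)
    save("regions", regions_to_frame(regions), index=False)
    save("patches", regions_to_frame(patches), index=False)
    save("correlations", correlations)
    save("evidence", evidence)
    save("candidates", candidates, index=False)
    paths["regions_bed"] = outdir / "regions.bed"
    rsio.write_regions_bed(regions + patches, paths["regions_bed"], header)
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(json.dumps(run_log, indent=1, sort_keys=True))

    return PipelineResult(
        contrasts=contrasts,
        call_summary=call_summary,
        breadth=breadth,
        profiles=profiles,
        model=model,
        assignment=assignment,
        flagged_clusters=flagged,
        co_clustered=co_clustered,
        enrichment=enrichment,
        regions=regions,
        patches=patches,
        correlations=correlations,
        evidence=evidence,
        candidates=candidates,
        run_log=run_log,
        output_paths=paths,
    )
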