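"""Synthetic induction experiments with planted ground truth.

Emulates the study design the pipeline targets: induced vs. uninduced control
cultures of a cellulolytic fungus sampled at 0/6/17 h with four biological
replicates, several inducing substrates, gene-wise log2 induction effects
organized into co-expression clusters, a genome laid out on scaffolds with
planted co-localized regions, a chemostat comparison block with a known
rate-correlated gene subset, and a planted set of "regulator" genes carrying
every evidence signature the downstream screen looks for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    CONTROL_SUBSTRATE,
    ExpressionDataset,
    GeneLocus,
    RateSeries,
    SyntheticTruth,
)

# genome tiling: fixed gene length / intergenic gap, 1-based inclusive
GENE_BP = 1000
GAP_BP = 500

# class vocabulary used by the planted annotations (mirrors the functional
# classes of fungal regulator candidates: Zn2-C6 binuclear cluster TFs etc.)
REGULATOR_CLASS = "fungal_C6_TF"
REGULATOR_DOMAIN = "IPR001138"
CAZY_CLASS = "CAZy"
CAZY_DOMAIN = "IPR001547"
TRANSPORTER_CLASS = "sugar_transporter"
TRANSPORTER_DOMAIN = "IPR005828"

#: rank buffer kept free around each planted region so the planted regions are
#: the only co-localized same-cluster structure (one more than the scan's
#: default max member gap)
REGION_BUFFER = 6


def default_effect_matrix(
    n_clusters: int, n_substrates: int, amplitude: float = 2.0
) -> np.ndarray:
    """Per-cluster x per-substrate log2 induction amplitudes.

    Cluster 0 is induced on every substrate (the cellulase-like reference
    cluster), cluster 1 on all but the last (hemicellulase-like); later
    clusters get rotated substrate blocks with occasional repression so the
    standardized profiles are mutually distinct.
    """
    rows = []
    for j in range(n_clusters):
        row = np.zeros(n_substrates)
        if j == 0:
            row[:] = amplitude
        elif j == 1:
            row[: max(1, n_substrates - 1)] = amplitude
        else:
            width = max(1, (n_substrates + 1) // 2)
            start = (j - 2) % n_substrates
            sign = -1.0 if j % 3 == 2 else 1.0
            for t in range(width):
                row[(start + t) % n_substrates] = sign * amplitude
        rows.append(row)
    return np.vstack(rows)


@dataclass
class SimulationConfig:
    """Fully specifies one synthetic study (genome + arrays + chemostat).

    Defaults reproduce the package's reference study conditions: 2,000 genes
    on 20 scaffolds, four inducing substrates sampled at 0/6/17 h with four
    biological replicates against a shared uninduced control, six planted
    co-expression clusters of 60 genes with log2 effects of magnitude 2,
    residual noise 0.5 on the log2 scale, 20 planted co-localized regions of
    five genes hosting 20 planted regulator genes, 2.5% of the genome tagged
    with the regulatory domain class, and a six-condition chemostat block.
    """

    n_genes: int = 2000
    n_scaffolds: int = 20
    substrates: Sequence[str] = ("avicel", "wheat", "spruce", "sophorose")
    time_points_h: Sequence[float] = (0.0, 6.0, 17.0)
    n_replicates: int = 4
    n_clusters: int = 6
    cluster_sizes: Sequence[int] | None = None  # default: 60 per cluster
    effect_log2: float | Sequence[float] | np.ndarray | None = None
    noise_sd: float = 0.5
    n_regions: int = 20
    region_span: int = 5
    n_regulators: int = 20
    regulatory_class_fraction: float = 0.025
    rate_profile: Sequence[float] = (0.015, 0.025, 0.035, 0.045, 0.055, 0.065)
    chemostat_slope_log2: float = 1.0  # log2 units per sd of the rate profile
    chemostat_noise_sd: float = 0.25
    time_profiles: Sequence[str] | None = None  # per cluster: early | late
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            self.cluster_sizes = [min(60, self.n_genes // max(1, self.n_clusters))] * self.n_clusters
        self.cluster_sizes = list(self.cluster_sizes)
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        self.effect_matrix = self._resolve_effects()
        if self.time_profiles is None:
            self.time_profiles = [
                "early" if j % 2 == 0 else "late" for j in range(self.n_clusters)
            ]
        self.time_profiles = list(self.time_profiles)
        self.validate()

    def _resolve_effects(self) -> np.ndarray:
        n_s = len(self.substrates)
        eff = self.effect_log2
        if eff is None:
            return default_effect_matrix(self.n_clusters, n_s)
        eff = np.asarray(eff, dtype=float)
        if eff.ndim == 0:
            return np.full((self.n_clusters, n_s), float(eff))
        if eff.ndim == 1:
            if len(eff) != self.n_clusters:
                raise ValueError("1-D effect_log2 must have one entry per cluster")
            return np.repeat(eff[:, None], n_s, axis=1)
        if eff.shape != (self.n_clusters, n_s):
            raise ValueError(
                f"effect_log2 shape {eff.shape} != (n_clusters, n_substrates)"
            )
        return eff

    def validate(self) -> None:
        for name in ("n_genes", "n_scaffolds", "n_replicates", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        if sum(self.cluster_sizes) > self.n_genes:
            raise ValueError("sum(cluster_sizes) exceeds n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.regulatory_class_fraction <= 1:
            raise ValueError("regulatory_class_fraction must be in [0, 1]")
        if self.n_regions > 0 and self.region_span < 3:
            raise ValueError("region_span must be >= 3 (a region needs >=3 genes)")
        if self.n_regulators > self.n_regions:
            raise ValueError(
                "each planted regulator needs its own planted region "
                f"(n_regulators={self.n_regulators} > n_regions={self.n_regions})"
            )
        if len(self.rate_profile) >= 1 and len(set(self.rate_profile)) < 2 and len(self.rate_profile) >= 3:
            raise ValueError("rate_profile values must not all be equal")
        bad = set(self.time_profiles) - {"early", "late"}
        if bad:
            raise ValueError(f"unknown time profiles: {sorted(bad)}")


@dataclass
class SyntheticDataset:
    """A complete synthetic study plus its planted ground truth."""

    expression: ExpressionDataset
    loci: list[GeneLocus]
    annotations: pd.DataFrame  # gene_id, class_label, domain_id
    reference_genes: list[str]
    chemostat: RateSeries
    proteome_flags: pd.Series  # gene -> {-1, 0, +1}
    truth: SyntheticTruth
    config: SimulationConfig = field(repr=False, default=None)


def _scaffold_sizes(n_genes: int, n_scaffolds: int) -> list[int]:
    base, extra = divmod(n_genes, n_scaffolds)
    return [base + (1 if i < extra else 0) for i in range(n_scaffolds)]


def _place_regions(config: SimulationConfig, sizes: list[int]) -> list[dict]:
    """Deterministically place planted regions, round-robin over scaffolds.

    Regions occupy ``region_span`` consecutive ranks and keep ``REGION_BUFFER``
    ranks free before the next region on the same scaffold. Raises if the
    requested regions cannot fit.
    """
    span, buf = config.region_span, REGION_BUFFER
    capacity = [max(0, (g + buf) // (span + buf)) for g in sizes]
    if config.n_regions > sum(capacity):
        raise ValueError(
            f"cannot place {config.n_regions} regions of span {span} on "
            f"{config.n_scaffolds} scaffolds (capacity {sum(capacity)})"
        )
    used = [0] * len(sizes)
    regions = []
    scaf = 0
    for r in range(config.n_regions):
        while used[scaf] >= capacity[scaf]:
            scaf = (scaf + 1) % len(sizes)
        first = used[scaf] * (span + buf)
        regions.append(
            {
                "region_id": f"region_{r:03d}",
                "scaffold_index": scaf,
                "first_rank": first,
                "last_rank": first + span - 1,
                # planted regions alternate between the two reference clusters
                "cluster": r % min(2, config.n_clusters),
            }
        )
        used[scaf] += 1
        scaf = (scaf + 1) % len(sizes)
    return regions


def _effect_time_factor(profile: str, t: float, times: Sequence[float]) -> float:
    if t <= 0:
        return 0.0
    if profile == "late":
        return 1.0 if t >= max(times) else 0.0
    return 1.0


def simulate_experiment(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete synthetic study from ``config``.

    The same config and seed always produce a bitwise-identical dataset.
    Planted-cluster genes are laid out contiguously inside the planted
    regions; remaining cluster members are spread over the leftover ranks
    with spacing wider than the scan's member gap, so the planted regions
    are the only co-localized same-cluster structure; background genes fill
    every remaining slot.
    """
    master = np.random.default_rng(config.rng_seed)
    seeds = master.integers(0, 2**31 - 1, size=3)
    # noise realizations vary with the seed; the planted truth structure
    # (layout, annotations) is a function of the config alone, so two seeds
    # share identical ground truth
    rng_layout = np.random.default_rng(1_000_003)
    rng_annot = np.random.default_rng(1_000_033)
    rng_baseline = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])
    rng_chemo = np.random.default_rng(seeds[2])

    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    sizes = _scaffold_sizes(n, config.n_scaffolds)
    regions = _place_regions(config, sizes)

    # map (scaffold, rank) -> flat gene index; genes are numbered scaffold by
    # scaffold in rank order so flat index also orders the genome
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    flat = lambda scaf, rank: int(offsets[scaf] + rank)  # noqa: E731

    labels = np.full(n, -1, dtype=int)  # -1 = background
    roles = np.array(["other"] * n, dtype=object)
    regulator_ids: list[str] = []
    reference_ids: list[str] = []
    region_extents: list[dict] = []

    # demand check: region genes consume their cluster's quota
    demand = np.zeros(config.n_clusters, dtype=int)
    for reg in regions:
        demand[reg["cluster"]] += config.region_span
    for j in range(config.n_clusters):
        if demand[j] > config.cluster_sizes[j]:
            raise ValueError(
                f"cluster {j} needs {demand[j]} region genes but has size "
                f"{config.cluster_sizes[j]}"
            )

    in_buffer = np.zeros(n, dtype=bool)
    for r_idx, reg in enumerate(regions):
        scaf, first = reg["scaffold_index"], reg["first_rank"]
        member_idx = [flat(scaf, first + k) for k in range(config.region_span)]
        labels[member_idx] = reg["cluster"]
        lo = max(0, first - REGION_BUFFER + 1)
        hi = min(sizes[scaf] - 1, reg["last_rank"] + REGION_BUFFER - 1)
        for rank in range(lo, hi + 1):
            in_buffer[flat(scaf, rank)] = True
        # role layout inside a region: a CAZy gene, a sugar transporter, then
        # (for regulator-hosting regions) the planted regulator, rest CAZy/other
        roles[member_idx[0]] = "CAZy"
        if config.region_span > 1:
            roles[member_idx[1]] = "transporter"
        hosts_regulator = r_idx < config.n_regulators
        for k in range(2, config.region_span):
            roles[member_idx[k]] = "CAZy" if k % 2 == 1 else "other"
        if hosts_regulator:
            roles[member_idx[2]] = "regulator"
            regulator_ids.append(gene_ids[member_idx[2]])
        reference_ids.append(gene_ids[member_idx[0]])
        region_extents.append(
            {
                "region_id": reg["region_id"],
                "scaffold": f"scaffold_{scaf + 1}",
                "cluster": int(reg["cluster"]),
                "first_rank": int(first),
                "last_rank": int(reg["last_rank"]),
                "gene_ids": [gene_ids[i] for i in member_idx],
            }
        )

    # scatter the remaining cluster members over free, non-buffer ranks with
    # a stride wide enough that no two scattered members are within the
    # scan's member gap of each other or of a planted region
    remaining = [config.cluster_sizes[j] - demand[j] for j in range(config.n_clusters)]
    n_scatter = int(sum(remaining))
    free = np.nonzero((labels < 0) & ~in_buffer)[0]
    if n_scatter > 0:
        if n_scatter > len(free):
            raise ValueError(
                f"not enough free gene slots ({len(free)}) for {n_scatter} "
                "scattered cluster members"
            )
        stride = max(1, len(free) // n_scatter)
        slots = free[::stride][:n_scatter]
        scatter_labels = np.repeat(
            np.arange(config.n_clusters), remaining
        )
        rng_layout.shuffle(scatter_labels)
        labels[slots] = scatter_labels

    # genome coordinates: fixed tiling, alternating strand
    loci: list[GeneLocus] = []
    for scaf_i, g_count in enumerate(sizes):
        for rank in range(g_count):
            i = flat(scaf_i, rank)
            start = 1 + rank * (GENE_BP + GAP_BP)
            loci.append(
                GeneLocus(
                    gene_id=gene_ids[i],
                    scaffold=f"scaffold_{scaf_i + 1}",
                    start=start,
                    end=start + GENE_BP - 1,
                    strand="+" if rank % 2 == 0 else "-",
                    rank=rank,
                )
            )

    # expression matrix
    times = list(config.time_points_h)
    baseline = rng_baseline.normal(8.0, 1.5, size=n)
    columns: list[str] = []
    design_rows: list[dict] = []
    signal_cols: list[np.ndarray] = []

    def add_sample(name, substrate, t, rep, role, effect_col):
        columns.append(name)
        design_rows.append(
            {"sample_id": name, "substrate": substrate, "time_h": t,
             "replicate": rep, "role": role}
        )
        signal_cols.append(effect_col)

    for substrate_i, substrate in enumerate(config.substrates):
        for t in times:
            for rep in range(1, config.n_replicates + 1):
                eff = np.zeros(n)
                mask = labels >= 0
                if mask.any():
                    cl = labels[mask]
                    factors = np.array(
                        [
                            _effect_time_factor(config.time_profiles[c], t, times)
                            for c in cl
                        ]
                    )
                    eff[mask] = config.effect_matrix[cl, substrate_i] * factors
                add_sample(
                    f"{substrate}_t{t:g}_r{rep}", substrate, t, rep, "induced", eff
                )
    for t in times:
        for rep in range(1, config.n_replicates + 1):
            add_sample(
                f"control_t{t:g}_r{rep}",
                CONTROL_SUBSTRATE,
                t,
                rep,
                "control",
                np.zeros(n),
            )

    signal = baseline[:, None] + np.column_stack(signal_cols)
    if config.noise_sd > 0:
        signal = signal + rng_noise.normal(0.0, config.noise_sd, size=signal.shape)
    matrix = pd.DataFrame(signal, index=pd.Index(gene_ids, name="gene_id"), columns=columns)
    design = pd.DataFrame(design_rows).set_index("sample_id")
    expression = ExpressionDataset(matrix=matrix, design=design)

    # chemostat block: regulators (alternating sign) and reference CAZy genes
    # (positive) track the specific protein production rate
    correlated: dict[str, int] = {}
    for k, gid in enumerate(regulator_ids):
        correlated[gid] = -1 if (k + 1) % 4 == 0 else 1
    for gid in reference_ids:
        correlated.setdefault(gid, 1)
    chemostat = simulate_chemostat(config, gene_ids, baseline, correlated, rng_chemo)

    proteome = pd.Series(0, index=pd.Index(gene_ids, name="gene_id"), dtype=int)
    for gid in regulator_ids:
        proteome[gid] = correlated[gid]

    # annotations: all planted regulators carry the regulatory domain class;
    # background genes are tagged at random up to the configured fraction
    n_reg_class = int(round(config.regulatory_class_fraction * n))
    tagged = list(regulator_ids)
    tagged_set = set(tagged)
    if n_reg_class > len(tagged):
        pool = [g for g in gene_ids if g not in tagged_set]
        extra = rng_annot.choice(len(pool), size=n_reg_class - len(tagged), replace=False)
        tagged.extend(pool[i] for i in sorted(extra))
    annot_rows = [
        {"gene_id": g, "class_label": REGULATOR_CLASS, "domain_id": REGULATOR_DOMAIN}
        for g in tagged
    ]
    for i, role in enumerate(roles):
        if role == "CAZy":
            annot_rows.append(
                {"gene_id": gene_ids[i], "class_label": CAZY_CLASS, "domain_id": CAZY_DOMAIN}
            )
        elif role == "transporter":
            annot_rows.append(
                {"gene_id": gene_ids[i], "class_label": TRANSPORTER_CLASS,
                 "domain_id": TRANSPORTER_DOMAIN}
            )
    annotations = pd.DataFrame(annot_rows).sort_values(
        ["gene_id", "class_label"], kind="stable"
    ).reset_index(drop=True)

    truth = SyntheticTruth(
        cluster_labels=pd.Series(labels, index=pd.Index(gene_ids, name="gene_id")),
        region_extents=region_extents,
        regulator_ids=regulator_ids,
        correlated_ids=correlated,
        reference_ids=reference_ids,
        roles=pd.Series(roles, index=pd.Index(gene_ids, name="gene_id")),
    )
    return SyntheticDataset(
        expression=expression,
        loci=loci,
        annotations=annotations,
        reference_genes=reference_ids,
        chemostat=chemostat,
        proteome_flags=proteome,
        truth=truth,
        config=config,
    )


def simulate_chemostat(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    baseline: np.ndarray,
    correlated: dict[str, int],
    rng: np.random.Generator,
) -> RateSeries:
    """Condition-level expression tracking the protein production rate.

    A designated gene subset follows ``baseline + sign * slope * z(rate)``
    plus noise, where z(rate) standardizes the rate profile; all other genes
    are independent of the rate.
    """
    rates = np.asarray(config.rate_profile, dtype=float)
    if len(rates) < 3:
        raise ValueError("chemostat screening needs >=3 conditions")
    conditions = [f"chemostat_{i + 1}" for i in range(len(rates))]
    z = (rates - rates.mean()) / rates.std()
    idx = {g: i for i, g in enumerate(gene_ids)}
    signal = np.repeat(baseline[:, None], len(rates), axis=1)
    for gid, sign in correlated.items():
        signal[idx[gid]] += sign * config.chemostat_slope_log2 * z
    if config.chemostat_noise_sd > 0:
        signal = signal + rng.normal(0.0, config.chemostat_noise_sd, size=signal.shape)
    expr = pd.DataFrame(signal, index=pd.Index(gene_ids, name="gene_id"), columns=conditions)
    return RateSeries(
        rates=pd.Series(rates, index=pd.Index(conditions, name="condition"), name="rate"),
        expression=expr,
    )
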