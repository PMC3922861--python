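"""Multi-evidence integration and ranking of candidate regulatory genes.

Five evidence criteria are assembled per gene:

1. induction by three or more of the inducing substrates;
2. co-clustering with the characterized cellulase/hemicellulase genes;
3. correlation of expression with the specific protein production rate;
4. proteome support (protein more/less abundant under high production);
5. genomic co-localization with cellulase/hemicellulase genes (membership
   in a co-regulated region, or a CAZy/transporter gene as direct neighbor).

Genes carrying a configured regulatory domain class and meeting at least
``min_criteria`` of the five are selected and ranked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CRITERIA = ("induction", "co_clustered", "correlation", "proteome", "location")
DEFAULT_MIN_CRITERIA = 3
DEFAULT_BREADTH_MIN = 3


def build_evidence(
    universe: list[str],
    breadth: pd.Series,
    co_clustered: list[str],
    corr: pd.DataFrame,
    region_gene_ids: set[str],
    neighbor_report: pd.DataFrame,
    regulatory_class_genes: set[str],
    proteome_flags: pd.Series | None = None,
    breadth_min: int = DEFAULT_BREADTH_MIN,
) -> pd.DataFrame:
    """Assemble the per-gene evidence table over one shared gene universe.

    Raises if any upstream output references genes outside the universe.
    """
    index = pd.Index(universe, name="gene_id")
    uni = set(universe)
    for name, ids in (
        ("induction breadth", set(breadth.index)),
        ("co-clustered set", set(co_clustered)),
        ("correlation screen", set(corr.index)),
        ("region members", set(region_gene_ids)),
        ("regulatory-class annotation", set(regulatory_class_genes)),
    ):
        stray = ids - uni
        if stray:
            raise ValueError(
                f"{name} references genes outside the universe: {sorted(stray)[:5]}"
            )
    if proteome_flags is None:
        proteome_flags = pd.Series(0, index=index, dtype=int)
    near = pd.Series(False, index=index)
    if len(neighbor_report):
        near_ids = neighbor_report.loc[
            neighbor_report["near_cazy_or_transporter"], "gene_id"
        ]
        near[near.index.isin(near_ids)] = True
    ev = pd.DataFrame(index=index)
    ev["regulatory_class"] = ev.index.isin(regulatory_class_genes)
    ev["induction_breadth"] = breadth.reindex(index, fill_value=0).astype(int)
    ev["co_clustered"] = ev.index.isin(co_clustered)
    ev["corr_pass"] = corr["passed"].reindex(index, fill_value=False).astype(bool)
    ev["corr_sign"] = corr["sign"].reindex(index, fill_value=0).astype(int)
    ev["proteome_flag"] = proteome_flags.reindex(index, fill_value=0).astype(int)
    ev["in_region"] = ev.index.isin(region_gene_ids)
    ev["near_cazy_or_transporter"] = near
    ev["crit_induction"] = ev["induction_breadth"] >= breadth_min
    ev["crit_co_clustered"] = ev["co_clustered"]
    ev["crit_correlation"] = ev["corr_pass"]
    ev["crit_proteome"] = ev["proteome_flag"] != 0
    ev["crit_location"] = ev["in_region"] | ev["near_cazy_or_transporter"]
    return ev


def select_candidates(
    evidence: pd.DataFrame,
    min_criteria: int = DEFAULT_MIN_CRITERIA,
    require_regulatory_class: bool = True,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score, rank and select candidate regulators from the evidence table.

    Score is the weighted sum of met criteria (uniform weights by default);
    candidates are ranked by score, then criteria count, then gene id, and
    ``selected`` marks genes meeting >= ``min_criteria``. Genes without the
    regulatory domain class are excluded when ``require_regulatory_class``.
    """
    crit_cols = [f"crit_{c}" for c in CRITERIA]
    if min_criteria > len(CRITERIA):
        raise ValueError(
            f"min_criteria={min_criteria} exceeds the {len(CRITERIA)} configured criteria"
        )
    if weights is None:
        weights = {c: 1.0 for c in CRITERIA}
    unknown = set(weights) - set(CRITERIA)
    if unknown:
        raise ValueError(f"weights for unknown criteria: {sorted(unknown)}")
    w = np.array([weights.get(c, 0.0) for c in CRITERIA])
    pool = evidence
    if require_regulatory_class:
        pool = evidence[evidence["regulatory_class"]]
    report = pool.rename_axis("gene_id").reset_index()
    crit = report[crit_cols].to_numpy(dtype=float)
    report["criteria_met"] = report[crit_cols].sum(axis=1).astype(int)
    report["score"] = crit @ w
    report["selected"] = report["criteria_met"] >= min_criteria
    report = report.sort_values(
        ["score", "criteria_met", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report
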