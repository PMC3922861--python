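"""Hypergeometric over-representation of functional classes in gene sets.

For a universe of N genes of which K carry a class label, and a selected set
of n genes with k carrying the label, the over-representation p-value is the
exact hypergeometric upper tail P(X >= k) and the fold enrichment is
(k/n) / (K/N) — e.g. a transcription-factor domain class covering 2.5% of the
genome but 5.9% of a co-expression cluster has fold 2.36.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    """Raw counts, fold enrichment and exact upper-tail p for one class."""

    class_label: str
    N: int  # universe size
    K: int  # class size in the universe
    n: int  # selected-set size
    k: int  # class members in the set
    fold: float
    p: float


def annotation_classes(annotations: pd.DataFrame) -> dict[str, set[str]]:
    """class_label -> set of gene ids, from a (gene_id, class_label, domain_id)
    annotation table."""
    return {
        label: set(group["gene_id"])
        for label, group in annotations.groupby("class_label")
    }


def class_enrichment(
    gene_set: Iterable[str],
    class_label: str,
    class_genes: set[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Exact hypergeometric upper-tail test of one class in one gene set."""
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set:
        raise ValueError("empty gene set")
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set not contained in universe: {sorted(stray)[:5]}")
    N = len(universe)
    K = len(class_genes & universe)
    n = len(gene_set)
    k = len(gene_set & class_genes)
    p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
    fold = 0.0 if K == 0 else (k / n) / (K / N)
    return EnrichmentResult(class_label=class_label, N=N, K=K, n=n, k=k,
                            fold=fold, p=min(p, 1.0))


def enrich_classes(
    gene_set: Iterable[str],
    annotations: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test every class against one gene set; BH-adjusted p reported alongside
    the raw p (the raw p remains primary)."""
    universe = set(universe)
    results = [
        class_enrichment(gene_set, label, genes, universe)
        for label, genes in sorted(annotations.items())
    ]
    frame = pd.DataFrame([r.__dict__ for r in results])
    if len(frame):
        frame["p_bh"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame
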