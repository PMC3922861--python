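"""Core in-memory containers shared across pipeline stages.

Expression data live in a :class:`ExpressionDataset` (log2 signal matrix plus
the sample design), gene coordinates in :class:`GeneLocus` records, and the
chemostat comparison block in a :class:`RateSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: role labels allowed in the sample design
ROLES = ("induced", "control")

#: substrate label carried by control cultures (controls are shared across
#: substrates; every induced (substrate, time) cell is contrasted against the
#: controls at the same time point)
CONTROL_SUBSTRATE = "control"


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes x samples) with its sample design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Normalized log2 signals, indexed by gene id, one column per sample.
    design : pandas.DataFrame
        Indexed by sample id with columns ``substrate`` (label), ``time_h``
        (non-negative float), ``replicate`` (int) and ``role`` (``induced``
        or ``control``).
    """

    matrix: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(self.matrix.columns) - set(self.design.index)
        if missing:
            raise ValueError(
                f"samples in matrix but absent from design: {sorted(missing)}"
            )
        extra = set(self.design.index) - set(self.matrix.columns)
        if extra:
            raise ValueError(
                f"samples in design but absent from matrix: {sorted(extra)}"
            )
        bad_roles = set(self.design["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles in design: {sorted(bad_roles)}")
        if self.matrix.isna().any().any():
            rows, cols = np.nonzero(self.matrix.isna().to_numpy())
            g = self.matrix.index[rows[0]]
            s = self.matrix.columns[cols[0]]
            raise ValueError(
                f"missing expression values (first at gene {g!r}, sample {s!r})"
            )
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def contrast_cells(self) -> list[tuple[str, float]]:
        """The (substrate, time) cells with induced samples, sorted."""
        induced = self.design[self.design["role"] == "induced"]
        cells = sorted(
            {(str(r.substrate), float(r.time_h)) for r in induced.itertuples()}
        )
        return cells


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position on a genome scaffold (1-based, inclusive)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "."
    rank: int = -1  # 0-based position in the scaffold's start-sorted order

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"inverted interval for {self.gene_id}: {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")


@dataclass
class RateSeries:
    """Chemostat comparison block: per-condition production rate + expression.

    ``rates`` maps condition id -> specific protein production rate (units are
    arbitrary but consistent); ``expression`` is a genes x conditions frame of
    condition-level log2 signals.
    """

    rates: pd.Series
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.rates) < 3:
            raise ValueError(
                f"need >=3 chemostat conditions, got {len(self.rates)}"
            )
        if self.rates.nunique() < 2:
            raise ValueError("chemostat rates are all equal")
        if list(self.expression.columns) != list(self.rates.index):
            raise ValueError("expression columns do not match rate conditions")


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside a synthetic dataset."""

    cluster_labels: pd.Series  # -1 = background (no planted effect)
    region_extents: list[dict]  # scaffold, cluster, gene_ids, start/end rank
    regulator_ids: list[str]
    correlated_ids: dict[str, int]  # gene id -> slope sign in chemostat block
    reference_ids: list[str]
    roles: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
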