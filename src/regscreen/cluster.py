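"""Fuzzy c-means co-expression clustering of temporal induction profiles.

Profiles (per-(substrate, time) mean log2 fold changes by default) are
row-standardized and clustered by fuzzy c-means, the soft clustering that
minimizes

    J_m = sum_i sum_j u_ij^m ||x_i - v_j||^2

under sum_j u_ij = 1, with the classic alternating updates

    u_ij = 1 / sum_k (||x_i - v_j|| / ||x_i - v_k||)^(2/(m-1))
    v_j  = sum_i u_ij^m x_i / sum_i u_ij^m.

The fuzzifier m controls membership softness (m -> 1 recovers hard k-means).
Clusters holding the reference cellulase/hemicellulase genes are then flagged
and the genes co-clustered with them extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_random_state

from .diffexpr import ContrastTable


@dataclass
class StandardizedProfiles:
    """Row-standardized profile matrix plus the zero-variance genes dropped."""

    matrix: pd.DataFrame
    dropped_genes: list[str] = field(default_factory=list)


def fold_change_profiles(contrasts: ContrastTable) -> pd.DataFrame:
    """Genes x (substrate, time) matrix of log2 fold changes vs. control."""
    t = contrasts.table.dropna(subset=["log2fc"])
    wide = t.pivot_table(
        index="gene_id", columns=["substrate", "time_h"], values="log2fc"
    )
    wide.columns = [f"{s}_t{h:g}" for s, h in wide.columns]
    return wide


def standardize(profiles: pd.DataFrame, tol: float = 0.0) -> StandardizedProfiles:
    """Row-wise z-scoring (sample sd, ddof=1); constant rows are dropped."""
    if profiles.shape[1] < 2:
        raise ValueError("profiles need >=2 columns to standardize")
    mu = profiles.mean(axis=1)
    sd = profiles.std(axis=1, ddof=1)
    keep = sd > tol
    dropped = profiles.index[~keep].tolist()
    z = profiles.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return StandardizedProfiles(matrix=z, dropped_genes=dropped)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy c-means clustering with seeded restarts.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c (>= 2).
    m : float
        Fuzzifier (> 1); 1.25 keeps memberships crisp enough for hard
        assignment while retaining graded membership information.
    tol : float
        Convergence threshold on max |delta U| between iterations.
    max_iter : int
        Iteration cap per restart.
    n_init : int
        Number of seeded restarts; the run with the lowest final J_m wins.
    random_state : int, RandomState or None
        Seeds the restarts; centroids are initialized from c distinct rows.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    membership_ : ndarray of shape (n_samples, n_clusters)
        Row-stochastic membership matrix U.
    labels_ : ndarray of shape (n_samples,)
        Hard labels, argmax over memberships (ties to the lowest index).
    objective_trace_ : ndarray
        J_m after each membership update of the winning restart
        (non-increasing).
    n_iter_ : int
    """

    def __init__(
        self,
        n_clusters: int = 8,
        m: float = 1.25,
        tol: float = 1e-5,
        max_iter: int = 300,
        n_init: int = 3,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, V: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        U = np.zeros_like(d2)
        zero = d2 <= 0
        coincident = zero.any(axis=1)
        if coincident.any():
            # a point sitting exactly on a centroid gets full membership on
            # the first coincident centroid
            first = np.argmax(zero[coincident], axis=1)
            U[np.nonzero(coincident)[0], first] = 1.0
        reg = ~coincident
        if reg.any():
            w = d2[reg] ** (-1.0 / (self.m - 1.0))
            U[reg] = w / w.sum(axis=1, keepdims=True)
        return U, d2

    def _objective(self, U: np.ndarray, d2: np.ndarray) -> float:
        return float(((U**self.m) * d2).sum())

    def _single_fit(self, X: np.ndarray, rng: np.random.Generator):
        n = X.shape[0]
        idx = rng.choice(n, size=self.n_clusters, replace=False)
        V = X[idx].copy()
        U, d2 = self._memberships(X, V)
        trace = [self._objective(U, d2)]
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            Um = U**self.m
            mass = Um.sum(axis=0)
            # a cluster with no membership mass (all points coincident with
            # another centroid) keeps its previous centroid
            empty = mass <= 0
            mass[empty] = 1.0
            V_new = (Um.T @ X) / mass[:, None]
            V_new[empty] = V[empty]
            V = V_new
            U_new, d2 = self._memberships(X, V)
            trace.append(self._objective(U_new, d2))
            delta = np.abs(U_new - U).max()
            U = U_new
            if delta < self.tol:
                break
        return U, V, np.asarray(trace), n_iter

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_all_finite=True)
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.n_clusters >= X.shape[0]:
            raise ValueError(
                f"n_clusters={self.n_clusters} must be < n_samples={X.shape[0]}"
            )
        rs = check_random_state(self.random_state)
        rng = np.random.default_rng(rs.randint(0, 2**31 - 1))
        best = None
        for _ in range(max(1, self.n_init)):
            U, V, trace, n_iter = self._single_fit(X, rng)
            if best is None or trace[-1] < best[2][-1]:
                best = (U, V, trace, n_iter)
        U, V, trace, n_iter = best
        self.membership_ = U
        self.cluster_centers_ = V
        self.labels_ = U.argmax(axis=1)
        self.objective_trace_ = trace
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Memberships of new profiles against the fitted centroids."""
        check_is_fitted(self, "cluster_centers_")
        X = check_array(X, dtype=np.float64)
        U, _ = self._memberships(X, self.cluster_centers_)
        return U

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass
class ClusterAssignment:
    """Hard cluster per gene with the core-membership flag."""

    table: pd.DataFrame  # gene_id index; columns cluster, max_membership, core

    @property
    def labels(self) -> pd.Series:
        return self.table["cluster"]


def assign_clusters(
    model: FuzzyCMeans, gene_ids: pd.Index, alpha: float = 0.5
) -> ClusterAssignment:
    """Harden fuzzy memberships: argmax cluster (ties to the lowest cluster
    index) and a core flag for genes whose top membership reaches ``alpha``."""
    check_is_fitted(model, "membership_")
    U = model.membership_
    if U.shape[0] != len(gene_ids):
        raise ValueError("gene_ids length does not match fitted memberships")
    top = U.max(axis=1)
    table = pd.DataFrame(
        {
            "cluster": U.argmax(axis=1),
            "max_membership": top,
            "core": top >= alpha,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ClusterAssignment(table=table)


def reference_clusters(
    assignment: ClusterAssignment,
    reference_gene_ids: list[str],
    coverage: float = 0.9,
) -> tuple[list[int], list[str]]:
    """Clusters that jointly hold >= ``coverage`` of the reference genes.

    Clusters are ranked by reference-member count (ties to the lower id) and
    the smallest prefix whose cumulative count reaches ``coverage`` of the
    references present is flagged. Returns the flagged cluster ids and all
    non-reference genes sharing them (the co-clustered set).
    """
    refs = [g for g in reference_gene_ids if g in assignment.table.index]
    if not reference_gene_ids:
        raise ValueError("reference gene set is empty")
    if not refs:
        raise ValueError("no reference genes present in the cluster assignment")
    counts = (
        assignment.table.loc[refs, "cluster"].value_counts().sort_index()
    )
    ranked = counts.sort_values(ascending=False, kind="stable")
    need = coverage * len(refs)
    flagged: list[int] = []
    covered = 0
    for cluster_id, cnt in ranked.items():
        flagged.append(int(cluster_id))
        covered += cnt
        if covered >= need:
            break
    in_flagged = assignment.table["cluster"].isin(flagged)
    ref_set = set(refs)
    co_clustered = [
        g for g in assignment.table.index[in_flagged] if g not in ref_set
    ]
    return sorted(flagged), co_clustered
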