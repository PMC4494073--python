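"""Co-expression clustering and eigengene summaries.

Acclimation-associated genes are grouped by average-linkage hierarchical
clustering on the Spearman dissimilarity d = 1 - rho, with the tree cut
at height 1 - rho_threshold so that merged groups keep average rank
correlation above the threshold. Each retained cluster is summarized by
its eigengene: the centered first-principal-component score vector over
samples, computed on gene-standardized expression so every member gene
carries equal weight. The eigengene's sign is oriented to correlate
positively with the cluster's mean standardized profile, removing the
eigenvector sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .design import ExperimentDesign, ValidationError
from .permtest import permutation_anova

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClusterSet:
    """Gene->cluster assignment plus per-cluster eigengene summaries."""

    membership: pd.Series = field(repr=False)  # gene_id -> label or "unassigned"
    eigengenes: pd.DataFrame = field(repr=False)  # clusters x samples, centered
    variance_explained: pd.Series = field(repr=False)

    @property
    def labels(self) -> list[str]:
        return list(self.eigengenes.index)

    def members(self, label: str) -> pd.Index:
        return self.membership.index[self.membership == label]

    def sizes(self) -> pd.Series:
        counts = self.membership[self.membership != UNASSIGNED].value_counts()
        return counts.reindex(self.labels).astype(int)


def spearman_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Spearman correlation (midranks for ties)."""
    if expr.shape[0] < 2 or expr.shape[1] < 3:
        raise ValidationError(
            f"need >=2 genes and >=3 samples for correlations, got {expr.shape}"
        )
    arr = expr.to_numpy(dtype=float)
    const = arr.std(axis=1) == 0
    if const.any():
        raise ValidationError(
            f"constant gene(s) have undefined correlations: "
            f"{list(expr.index[const][:5])}"
        )
    rho = spearmanr(arr, axis=1).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two variables
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=expr.index, columns=expr.index)


def cluster_genes(
    corr: pd.DataFrame,
    rho_threshold: float = 0.6,
    min_size: int = 10,
    linkage_method: str = "average",
) -> pd.Series:
    """Cut an average-linkage tree on 1 - rho at height 1 - rho_threshold.

    Returns a membership Series; clusters with fewer than ``min_size``
    members are relabeled ``unassigned``. Retained clusters are named
    ``cluster_1``, ``cluster_2``, ... by decreasing size.
    """
    if min_size < 2:
        raise ValidationError(f"min_size must be >= 2, got {min_size}")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw = hierarchy.fcluster(z, t=1.0 - rho_threshold, criterion="distance")
    membership = pd.Series(UNASSIGNED, index=corr.index, dtype=object, name="cluster")
    counts = pd.Series(raw).value_counts()
    keep = counts[counts >= min_size]
    # stable ordering: by size desc, then by first-member position for ties
    order = sorted(
        keep.index,
        key=lambda lab: (-keep[lab], int(np.flatnonzero(raw == lab)[0])),
    )
    for rank, lab in enumerate(order, start=1):
        membership.iloc[np.flatnonzero(raw == lab)] = f"cluster_{rank}"
    return membership


def eigengene(
    expr: pd.DataFrame, standardize: bool = True
) -> tuple[pd.Series, float, int]:
    """First-PC summary of one cluster's expression.

    Returns ``(scores, variance_explained, sign)`` where ``scores`` is the
    centered per-sample PC1 score vector, ``variance_explained`` the
    leading eigenvalue over the total, and ``sign`` the orientation factor
    (+1/-1) applied so the scores correlate positively with the cluster's
    mean standardized profile.
    """
    if expr.shape[0] < 2:
        raise ValidationError("eigengene needs a cluster of >=2 genes")
    arr = expr.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValidationError(
            f"constant gene(s) in cluster: {list(expr.index[sd == 0][:5])}"
        )
    centered = arr - arr.mean(axis=1, keepdims=True)
    X = centered / sd[:, None] if standardize else centered
    # samples are observations: SVD of (samples x genes)
    u, s, _ = np.linalg.svd(X.T, full_matrices=False)
    scores = u[:, 0] * s[0]
    scores = scores - scores.mean()
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = X.mean(axis=0)
    orient = np.sign(np.dot(scores, mean_profile - mean_profile.mean()))
    sign = int(orient) if orient != 0 else 1
    scores = scores * sign
    return (
        pd.Series(scores, index=expr.columns, name="eigengene"),
        var_explained,
        sign,
    )


def build_cluster_set(
    expr: pd.DataFrame,
    rho_threshold: float = 0.6,
    min_size: int = 10,
    linkage_method: str = "average",
    standardize: bool = True,
) -> ClusterSet:
    """Full clustering pass: correlations, tree cut, eigengenes."""
    corr = spearman_matrix(expr)
    membership = cluster_genes(corr, rho_threshold, min_size, linkage_method)
    labels = sorted(
        set(membership) - {UNASSIGNED}, key=lambda s: int(s.rsplit("_", 1)[1])
    )
    eig_rows, ve = {}, {}
    for lab in labels:
        genes = membership.index[membership == lab]
        scores, var_exp, _ = eigengene(expr.loc[genes], standardize=standardize)
        eig_rows[lab] = scores
        ve[lab] = var_exp
    eig = (
        pd.DataFrame(eig_rows).T
        if eig_rows
        else pd.DataFrame(columns=expr.columns)
    )
    eig.index.name = "cluster"
    return ClusterSet(
        membership,
        eig,
        pd.Series(ve, dtype=float, name="variance_explained"),
    )


def eigengene_anova(
    eig: pd.Series,
    design: ExperimentDesign,
    n_permutations: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> pd.Series:
    """Permutational treatment x day ANOVA (with interaction) on an eigengene."""
    return permutation_anova(
        eig,
        design,
        interaction=True,
        n_permutations=n_permutations,
        seed=seed,
        exhaustive=exhaustive,
    )
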