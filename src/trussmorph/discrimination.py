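"""Multivariate discrimination among species groups.

Stages
------
* Correlation-matrix PCA with an eigenvalue retention threshold of 0.7
  (Jolliffe's rule: correlation-matrix components with eigenvalue below about
  0.7 carry less information than a single standardized variable).
* Canonical discriminant function analysis (DFA): eigen-decomposition of
  W⁻¹B, with W the pooled within-group scatter and B the between-group
  scatter; classification assigns each specimen to the group whose centroid
  is closest in Mahalanobis distance under the pooled within-group covariance
  with equal priors.  Resubstitution and leave-one-out (each specimen
  classified by a model refitted without it) classification matrices are both
  produced.
* Squared Mahalanobis distances between group centroids with a Hotelling-type
  F approximation for pairwise significance.
* UPGMA (size-weighted average-linkage) clustering of the centroid distance
  matrix into an ultrametric dendrogram, exportable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from trussmorph.errors import DomainError, SingularityError, ValidationError
from trussmorph.size_correction import CorrectedTable


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAConfig:
    retention_threshold: float = 0.7
    matrix: str = "correlation"  # or "covariance"

    def __post_init__(self) -> None:
        if self.retention_threshold <= 0:
            raise DomainError("retention_threshold must be positive")
        if self.matrix not in ("correlation", "covariance"):
            raise DomainError(f"unknown matrix type {self.matrix!r}")


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    variance_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame  # variables × components
    scores: pd.DataFrame  # specimens × components
    retained: int

    def retained_variance_pct(self) -> float:
        return float(self.cumulative_pct[self.retained - 1]) if self.retained else 0.0


def pca(table: CorrectedTable | pd.DataFrame, config: PCAConfig | None = None) -> PCAResult:
    """Principal component analysis of the (default) correlation matrix.

    Components are sorted by descending eigenvalue; ``retained`` counts
    eigenvalues at or above the retention threshold (boundary inclusive).
    """
    config = config or PCAConfig()
    data = table.values if isinstance(table, CorrectedTable) else table
    X = data.values.astype(float)
    names = list(data.columns)
    index = data.index

    sd = X.std(axis=0, ddof=1)
    if config.matrix == "correlation":
        constant = [names[i] for i in np.flatnonzero(sd == 0)]
        if constant:
            raise ValidationError(
                f"constant variables under correlation-matrix PCA: {constant}"
            )
        Z = (X - X.mean(axis=0)) / sd
        mat = np.corrcoef(X, rowvar=False)
    else:
        Z = X - X.mean(axis=0)
        mat = np.cov(X, rowvar=False)
    mat = np.atleast_2d(mat)

    evals, evecs = linalg.eigh(mat)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive
    for c in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, c]))
        if evecs[i, c] < 0:
            evecs[:, c] = -evecs[:, c]

    total = evals.sum()
    variance_pct = 100.0 * evals / total
    cumulative = np.cumsum(variance_pct)
    retained = int(np.sum(evals >= config.retention_threshold - 1e-12))

    comp_names = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=names, columns=comp_names)
    scores = pd.DataFrame(Z @ evecs, index=index, columns=comp_names)
    return PCAResult(
        eigenvalues=evals,
        variance_pct=variance_pct,
        cumulative_pct=cumulative,
        loadings=loadings,
        scores=scores,
        retained=retained,
    )


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------


@dataclass
class ClassificationMatrix:
    """Row-normalized confusion matrix in percent (rows: true species)."""

    percentages: pd.DataFrame
    counts: pd.DataFrame
    overall_pct: float

    def to_csv(self, path: str | Path) -> None:
        out = self.percentages.copy()
        out["Total"] = out.sum(axis=1)
        out.to_csv(path, index_label="species")


@dataclass
class DFAResult:
    canonical_coefficients: pd.DataFrame  # standardized, variables × functions
    raw_coefficients: pd.DataFrame
    group_centroids: pd.DataFrame  # groups × functions (canonical space)
    eigenvalues: np.ndarray
    classification_original: ClassificationMatrix
    classification_loocv: ClassificationMatrix | None
    top_discriminators: list[str]

    def scores(self, table: CorrectedTable) -> pd.DataFrame:
        X = table.values[self.raw_coefficients.index].values
        return pd.DataFrame(
            (X - self._grand_mean) @ self.raw_coefficients.values,
            index=table.values.index,
            columns=self.raw_coefficients.columns,
        )

    _grand_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _scatter_matrices(
    X: np.ndarray, labels: np.ndarray, groups: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Pooled within-group (W) and between-group (B) scatter, grand mean, group means."""
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means: dict[str, np.ndarray] = {}
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        means[g] = mg
        dev = Xg - mg
        W += dev.T @ dev
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    return W, B, grand, means


def _solve_pooled(
    W: np.ndarray, n: int, k: int, ridge: float | None
) -> np.ndarray:
    """Inverse of the pooled within-group covariance S = W/(n-k)."""
    S = W / (n - k)
    if ridge:
        S = S + ridge * np.eye(S.shape[0])
    p = S.shape[0]
    if n - k < p and not ridge:
        raise SingularityError(
            f"pooled within-group covariance is singular ({p} variables but only "
            f"{n - k} within-group degrees of freedom); reduce variables, use "
            "PCA scores, or enable the ridge flag"
        )
    try:
        return linalg.inv(S)
    except linalg.LinAlgError as exc:
        raise SingularityError(
            "pooled within-group covariance is singular; reduce variables, use "
            "PCA scores, or enable the ridge flag"
        ) from exc


def _check_groups(labels: pd.Series, min_n: int = 2) -> list[str]:
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    counts = labels.value_counts()
    small = [g for g in groups if counts[g] < min_n]
    if small:
        raise ValidationError(f"groups with fewer than {min_n} specimens: {small}")
    return groups


def _classify(
    X: np.ndarray, means: dict[str, np.ndarray], Sinv: np.ndarray, groups: Sequence[str]
) -> list[str]:
    preds = []
    for x in X:
        d2 = {g: float((x - m) @ Sinv @ (x - m)) for g, m in means.items()}
        preds.append(min(groups, key=lambda g: (d2[g], g)))
    return preds


def _classification_matrix(
    true: pd.Series, pred: Sequence[str], groups: Sequence[str]
) -> ClassificationMatrix:
    counts = pd.DataFrame(0, index=list(groups), columns=list(groups), dtype=int)
    for t, p in zip(true, pred):
        counts.loc[t, p] += 1
    row_sums = counts.sum(axis=1)
    pct = counts.div(row_sums, axis=0) * 100.0
    overall = 100.0 * np.trace(counts.values) / counts.values.sum()
    return ClassificationMatrix(percentages=pct, counts=counts, overall_pct=float(overall))


def dfa_fit(
    table: CorrectedTable,
    groups: pd.Series | None = None,
    ridge: float | None = None,
    loocv: bool = False,
    n_top: int = 8,
) -> DFAResult:
    """Canonical discriminant analysis with resubstitution classification.

    Standardized coefficients scale the raw canonical weights by the pooled
    within-group standard deviation of each variable, making their magnitudes
    comparable; ``top_discriminators`` ranks variables by the maximum absolute
    standardized coefficient across functions (top ``n_top`` reported).
    """
    labels = table.species if groups is None else groups
    group_list = _check_groups(labels)
    X = table.values.values.astype(float)
    names = list(table.values.columns)
    n, p = X.shape
    k = len(group_list)

    W, B, grand, means = _scatter_matrices(X, labels.values, group_list)
    Sinv = _solve_pooled(W, n, k, ridge)

    # canonical functions: generalized eigenproblem B v = λ W v
    Wr = W + (ridge or 0.0) * (n - k) * np.eye(p)
    try:
        evals, evecs = linalg.eigh(B, Wr)
    except linalg.LinAlgError as exc:
        raise SingularityError(
            "within-group scatter not positive definite; reduce variables or "
            "enable the ridge flag"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_func = min(k - 1, p)
    evals = np.clip(evals[order][:n_func], 0, None)
    V = evecs[:, order][:, :n_func]
    # scale so pooled within-group variance of each canonical variate is 1
    within_var = np.diag(V.T @ (W / (n - k)) @ V)
    V = V / np.sqrt(np.where(within_var > 0, within_var, 1.0))
    for c in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, c]))
        if V[i, c] < 0:
            V[:, c] = -V[:, c]

    func_names = [f"DF{i + 1}" for i in range(n_func)]
    raw = pd.DataFrame(V, index=names, columns=func_names)
    pooled_sd = np.sqrt(np.diag(W / (n - k)))
    standardized = raw.mul(pooled_sd, axis=0)
    centroids = pd.DataFrame(
        {g: (means[g] - grand) @ V for g in group_list}, index=func_names
    ).T

    preds = _classify(X, means, Sinv, group_list)
    original = _classification_matrix(labels, preds, group_list)

    ranked = standardized.abs().max(axis=1).sort_values(ascending=False, kind="stable")
    top = list(ranked.index[:n_top])

    cv = dfa_loocv(table, labels, ridge=ridge) if loocv else None
    result = DFAResult(
        canonical_coefficients=standardized,
        raw_coefficients=raw,
        group_centroids=centroids,
        eigenvalues=evals,
        classification_original=original,
        classification_loocv=cv,
        top_discriminators=top,
    )
    result._grand_mean = grand
    return result


def dfa_loocv(
    table: CorrectedTable, groups: pd.Series | None = None, ridge: float | None = None
) -> ClassificationMatrix:
    """Leave-one-out classification: each specimen scored by a model fitted
    on all remaining specimens (the held-out group must not vanish, so every
    group needs at least 2 specimens)."""
    labels = table.species if groups is None else groups
    group_list = _check_groups(labels, min_n=2)
    X = table.values.values.astype(float)
    n, p = X.shape
    k = len(group_list)

    preds: list[str] = []
    lab = labels.values
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, li = X[mask], lab[mask]
        W, _, _, means = _scatter_matrices(Xi, li, group_list)
        Sinv = _solve_pooled(W, n - 1, k, ridge)
        preds.extend(_classify(X[i : i + 1], means, Sinv, group_list))
    return _classification_matrix(labels, preds, group_list)


# ---------------------------------------------------------------------------
# Mahalanobis centroid distances
# ---------------------------------------------------------------------------


@dataclass
class CentroidDistanceMatrix:
    """Squared Mahalanobis distances between group centroids, with p-values."""

    d2: pd.DataFrame
    p: pd.DataFrame
    group_sizes: dict[str, int]

    def to_csv(self, path: str | Path) -> None:
        """Distances above the diagonal, p-values below, as in the standard
        pairwise-matrix presentation."""
        labels = list(self.d2.index)
        out = pd.DataFrame("", index=labels, columns=labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    out.loc[a, b] = f"{self.d2.loc[a, b]:.4f}"
                elif i > j:
                    out.loc[a, b] = f"{self.p.loc[a, b]:.6g}"
        out.to_csv(path, index_label="species")


def mahalanobis_centroids(
    table: CorrectedTable,
    groups: pd.Series | None = None,
    ridge: float | None = None,
) -> CentroidDistanceMatrix:
    """Pairwise d²(g, h) = (m_g − m_h)ᵀ S⁻¹ (m_g − m_h) with pooled S.

    Significance uses the two-sample Hotelling-type approximation:
    F = ((n_g + n_h − p − 1) n_g n_h) / (p (n_g + n_h − 2)(n_g + n_h)) · d²
    on (p, n_g + n_h − p − 1) degrees of freedom.  When the second degree of
    freedom is not positive the p-value is reported as NaN.
    """
    labels = table.species if groups is None else groups
    group_list = _check_groups(labels)
    X = table.values.values.astype(float)
    n, p = X.shape
    k = len(group_list)
    W, _, _, means = _scatter_matrices(X, labels.values, group_list)
    Sinv = _solve_pooled(W, n, k, ridge)
    sizes = {g: int((labels == g).sum()) for g in group_list}

    d2 = pd.DataFrame(0.0, index=group_list, columns=group_list)
    pmat = pd.DataFrame(1.0, index=group_list, columns=group_list)
    for i, g in enumerate(group_list):
        for h in group_list[i + 1 :]:
            diff = means[g] - means[h]
            val = float(diff @ Sinv @ diff)
            d2.loc[g, h] = d2.loc[h, g] = val
            ng, nh = sizes[g], sizes[h]
            df2 = ng + nh - p - 1
            if df2 > 0 and val > 0:
                f = (df2 * ng * nh) / (p * (ng + nh - 2) * (ng + nh)) * val
                pv = float(stats.f.sf(f, p, df2))
            elif val == 0:
                pv = 1.0
            else:
                pv = float("nan")
            pmat.loc[g, h] = pmat.loc[h, g] = pv
    return CentroidDistanceMatrix(d2=d2, p=pmat, group_sizes=sizes)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class DendrogramNode:
    """Node of an ultrametric UPGMA tree.

    ``height`` is the cophenetic level: half the distance at which the two
    children merged.  Leaves have height 0 and a ``label``.
    """

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()

    def cophenetic(self) -> pd.DataFrame:
        """Pairwise cophenetic distances (2 × merge height) between leaves."""
        labels = sorted(self.leaves())
        mat = pd.DataFrame(0.0, index=labels, columns=labels)

        def walk(node: "DendrogramNode") -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    mat.loc[a, b] = mat.loc[b, a] = 2.0 * node.height
            return left + right

        walk(self)
        return mat

    def to_newick(self) -> str:
        def fmt(node: "DendrogramNode", parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(fmt(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(distances: CentroidDistanceMatrix | pd.DataFrame) -> DendrogramNode:
    """Size-weighted average-linkage agglomeration of a distance matrix.

    At each step the pair of clusters at minimal distance merges at height
    d/2; the distance from the merged cluster to any other is the
    member-count-weighted mean of the two constituent distances.  Ties break
    lexicographically on the sorted leaf labels of the candidate pair, so
    output is deterministic.
    """
    d = distances.d2 if isinstance(distances, CentroidDistanceMatrix) else distances
    if d.isna().any().any():
        raise ValidationError("NaN in distance matrix")
    labels = list(d.index)
    if len(labels) < 2:
        raise DomainError("need at least 2 taxa")
    if not np.allclose(d.values, d.values.T):
        raise ValidationError("distance matrix not symmetric")
    if not np.allclose(np.diag(d.values), 0):
        raise ValidationError("distance matrix diagonal not zero")

    clusters: dict[str, tuple[DendrogramNode, int]] = {
        lab: (DendrogramNode(height=0.0, label=lab), 1) for lab in labels
    }
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dist[frozenset((a, b))] = float(d.loc[a, b])

    def pair_key(pair: frozenset) -> tuple:
        return tuple(sorted(pair))

    while len(clusters) > 1:
        best = min(dist, key=lambda k: (dist[k], pair_key(k)))
        a, b = sorted(best)
        da, na = clusters.pop(a)
        db, nb = clusters.pop(b)
        h = dist.pop(best) / 2.0
        merged = DendrogramNode(height=h, children=(da, db))
        name = a  # internal key only; lexicographically first member
        new_dist: dict[frozenset, float] = {}
        for key, val in dist.items():
            if a in key or b in key:
                other = next(iter(key - {a, b}))
                partner = frozenset((name, other))
                prev_a = dist.get(frozenset((a, other)))
                prev_b = dist.get(frozenset((b, other)))
                if partner not in new_dist:
                    new_dist[partner] = (na * prev_a + nb * prev_b) / (na + nb)
            else:
                new_dist[key] = val
        dist = new_dist
        clusters[name] = (merged, na + nb)

    (root, _), = clusters.values()
    return root
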