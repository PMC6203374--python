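"""Generalized Procrustes alignment and relative-warp shape analysis.

Configurations are superimposed by translating centroids to the origin,
scaling to unit centroid size, and rotating each (proper rotations only, no
reflections) onto the running consensus; the consensus is re-estimated and
the loop repeats until it stabilizes.  The aligned coordinates live in the
tangent space around the consensus, where shape variation is analyzed.

Relative warps are principal components of that shape variation, optionally
weighted by spatial scale: the thin-plate-spline bending-energy matrix of the
consensus (kernel U(r) = r² log r²) supplies principal warps — eigenvectors
of bending energy on the non-affine subspace — and Procrustes residuals are
projected onto them with weight eigenvalue^(−α/2).  With α = 0 and the
uniform (affine) component included, relative warps coincide with an
ordinary PCA of the aligned residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from trussmorph.errors import DomainError, ValidationError
from trussmorph.landmark_io import LandmarkConfiguration


@dataclass
class ProcrustesFit:
    """Result of generalized Procrustes alignment.

    ``aligned`` is an ``(n, k, 2)`` array of superimposed configurations, each
    centered at the origin with centroid size 1; ``consensus`` is their
    coordinate-wise mean.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    species: list[str]
    iterations: int
    converged: bool

    def residuals(self) -> np.ndarray:
        """Per-specimen tangent-space deviations from the consensus, (n, k, 2).

        Raw deviations ``aligned − consensus`` are projected orthogonally to
        the similarity directions at the consensus (isotropic scaling and
        rotation); translation components vanish exactly because every
        aligned shape is centered.  This is the standard tangent projection,
        and it caps the nonzero shape dimensions at 2k − 4.
        """
        raw = (self.aligned - self.consensus[None, :, :]).reshape(len(self.aligned), -1)
        c = self.consensus.ravel()
        scale_dir = c / np.sqrt(c @ c)
        rot = np.column_stack([-self.consensus[:, 1], self.consensus[:, 0]]).ravel()
        rot_dir = rot / np.sqrt(rot @ rot)
        for d in (scale_dir, rot_dir):
            raw = raw - np.outer(raw @ d, d)
        return raw.reshape(self.aligned.shape)

    def procrustes_variance(self) -> float:
        """Total sample variance of shape: mean squared residual per specimen."""
        r = self.residuals()
        return float((r**2).sum() / len(r))


@dataclass
class RelativeWarpResult:
    bending_energy_eigenvalues: np.ndarray
    warp_scores: pd.DataFrame  # specimens × RW components
    variance_pct: np.ndarray
    singular_values: np.ndarray
    alpha: float
    uniform_included: bool

    @property
    def n_components(self) -> int:
        return self.warp_scores.shape[1]


def _center_scale(points: np.ndarray) -> tuple[np.ndarray, float]:
    centered = points - points.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size == 0:
        raise ValidationError("degenerate configuration: all landmarks coincident")
    return centered / size, size


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation (det +1) minimizing ||source R − target||."""
    u, _, vt = linalg.svd(source.T @ target)
    r = u @ vt
    if linalg.det(r) < 0:
        u[:, -1] = -u[:, -1]
        r = u @ vt
    return r


def gpa_align(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Iterative generalized least-squares Procrustes superimposition."""
    if len(configs) < 2:
        raise ValidationError("need at least 2 configurations")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValidationError(
                f"specimen {c.specimen_id!r}: landmark count {c.n_landmarks} != {k}"
            )

    shapes = np.empty((len(configs), k, 2))
    sizes = np.empty(len(configs))
    for i, c in enumerate(configs):
        scaled, size = _center_scale(c.points)
        shapes[i] = scaled
        sizes[i] = size

    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus, _ = _center_scale(new_consensus)
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # the reported consensus is the plain coordinate-wise mean of the aligned
    # shapes (the unit-size copy above is only the rotation target)
    consensus = shapes.mean(axis=0)
    if not converged:
        import logging

        logging.getLogger(__name__).warning(
            "GPA did not converge in %d iterations", max_iter
        )

    return ProcrustesFit(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        species=[c.species for c in configs],
        iterations=iterations,
        converged=converged,
    )


def species_consensus(
    fit: ProcrustesFit, groups: Sequence[str] | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-species mean aligned shape and its deviation from the grand consensus.

    Returns ``(means, deviations)``; both map species label → (k, 2) array.
    """
    labels = list(fit.species) if groups is None else list(groups)
    order = list(dict.fromkeys(labels))
    means: dict[str, np.ndarray] = {}
    deviations: dict[str, np.ndarray] = {}
    arr = np.asarray(labels)
    for g in order:
        mask = arr == g
        if not mask.any():
            raise ValidationError(f"empty species group {g!r}")
        means[g] = fit.aligned[mask].mean(axis=0)
        deviations[g] = means[g] - fit.consensus
    return means, deviations


def bending_energy_matrix(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin-plate-spline bending energy of a reference configuration.

    Returns ``(Be, eigenvalues, eigenvectors)`` where ``Be`` is the k × k
    bending-energy matrix (the upper-left block of L⁻¹), and the eigenpairs
    are sorted by ascending eigenvalue.  Affine deformations lie in the
    (three-dimensional) null space: the k − 3 eigenvectors with nonzero
    eigenvalue are the principal warps.
    """
    pts = np.asarray(consensus, dtype=float)
    k = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    r2 = (diff**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    Q = np.column_stack([np.ones(k), pts])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = linalg.inv(L)
    Be = Linv[:k, :k]
    Be = 0.5 * (Be + Be.T)
    evals, evecs = linalg.eigh(Be)
    return Be, evals, evecs


def _uniform_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2 columns, 2k rows) of the uniform shape subspace.

    The affine deformations of the consensus span a 4-dimensional space of
    2-D linear maps; removing the similarity part (isotropic scaling and
    rotation, which Procrustes alignment has already quotiented out) leaves
    the 2-dimensional uniform component.
    """
    k = consensus.shape[0]
    x, y = consensus[:, 0], consensus[:, 1]
    # flattened fields for the four generators of GL(2)
    gens = []
    for a, b, c, d in ((1, 0, 0, 0), (0, 1, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1)):
        field = np.column_stack([a * x + b * y, c * x + d * y]).ravel()
        gens.append(field)
    A = np.column_stack(gens)
    # similarity part: scaling (x, y) and rotation (−y, x)
    scale = np.column_stack([x, y]).ravel()
    rot = np.column_stack([-y, x]).ravel()
    S = np.column_stack([scale, rot])
    # project similarity out of the affine space, then orthonormalize
    P = np.eye(2 * k) - S @ linalg.pinv(S)
    U = P @ A
    q, r = linalg.qr(U, mode="economic")
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep][:, :2]


def relative_warps(
    fit: ProcrustesFit,
    alpha: float = 0.0,
    uniform_included: bool = True,
) -> RelativeWarpResult:
    """Relative-warp (shape PCA) analysis of a Procrustes fit.

    With ``alpha = 0`` and the uniform component included the warp scores are
    identical to principal-component scores of the aligned Procrustes
    residuals.  Nonzero ``alpha`` emphasizes large-scale (α > 0) or
    small-scale (α < 0) deformation.
    """
    n, k, _ = fit.aligned.shape
    if n < 3:
        raise DomainError("need at least 3 specimens for relative warps")
    residuals = fit.residuals().reshape(n, 2 * k)

    _, be_evals, be_evecs = bending_energy_matrix(fit.consensus)
    nonzero = be_evals > max(be_evals.max(), 1.0) * 1e-10
    pw_evals = be_evals[nonzero]
    pw_vecs = be_evecs[:, nonzero]  # k × (k−3) principal warps

    total_var = float((residuals**2).sum() / n)
    if total_var <= 1e-24:
        empty = pd.DataFrame(index=pd.Index(fit.specimen_ids, name="specimen_id"))
        return RelativeWarpResult(
            bending_energy_eigenvalues=pw_evals,
            warp_scores=empty,
            variance_pct=np.zeros(0),
            singular_values=np.zeros(0),
            alpha=alpha,
            uniform_included=uniform_included,
        )

    if alpha == 0.0 and uniform_included:
        weight = residuals
    else:
        res3 = residuals.reshape(n, k, 2)
        # scores of each specimen on each principal warp (x and y separately)
        proj = np.einsum("nkd,kw->nwd", res3, pw_vecs)
        proj = proj * (pw_evals[None, :, None] ** (-alpha / 2.0))
        blocks = [proj.reshape(n, -1)]
        if uniform_included:
            ub = _uniform_basis(fit.consensus)
            blocks.insert(0, residuals @ ub)
        weight = np.concatenate(blocks, axis=1)

    centered = weight - weight.mean(axis=0)
    u, s, vt = linalg.svd(centered, full_matrices=False)
    keep = s > s.max() * 1e-10
    u, s = u[:, keep], s[keep]
    for c in range(u.shape[1]):
        i = np.argmax(np.abs(u[:, c]))
        if u[i, c] < 0:
            u[:, c] = -u[:, c]
    scores = u * s
    var = s**2
    variance_pct = 100.0 * var / var.sum()
    cols = [f"RW{i + 1}" for i in range(scores.shape[1])]
    return RelativeWarpResult(
        bending_energy_eigenvalues=pw_evals,
        warp_scores=pd.DataFrame(
            scores, index=pd.Index(fit.specimen_ids, name="specimen_id"), columns=cols
        ),
        variance_pct=variance_pct,
        singular_values=s,
        alpha=alpha,
        uniform_included=uniform_included,
    )


def deformation_field(
    consensus: np.ndarray, target: np.ndarray, grid_points: int = 20
) -> dict:
    """Thin-plate-spline deformation of a grid carrying consensus → target.

    Returns a JSON-serializable dict with the source grid and its displaced
    image — the numeric equivalent of a deformation-grid plot.
    """
    pts = np.asarray(consensus, dtype=float)
    k = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    r2 = (diff**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    Q = np.column_stack([np.ones(k), pts])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = np.asarray(target, dtype=float)
    coefs = linalg.solve(L, rhs)

    lo, hi = pts.min(axis=0), pts.max(axis=0)
    pad = 0.05 * (hi - lo)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_points)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_points)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    d = grid[:, None, :] - pts[None, :, :]
    r2g = (d**2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        Kg = np.where(r2g > 0, r2g * np.log(r2g), 0.0)
    warped = Kg @ coefs[:k] + np.column_stack([np.ones(len(grid)), grid]) @ coefs[k:]
    return {
        "grid_shape": [grid_points, grid_points],
        "source": grid.tolist(),
        "warped": warped.tolist(),
    }
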