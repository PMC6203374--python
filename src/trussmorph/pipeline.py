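"""End-to-end orchestration of the traditional and truss analysis tracks.

``run_traditional`` takes a trait table through ratio/log size correction,
per-character ANOVA, correlation-matrix PCA, discriminant analysis with
leave-one-out cross-validation, Mahalanobis centroid distances and UPGMA
clustering.  ``run_truss`` does the same starting from landmark
configurations: full truss distances, SL-edge exclusion, allometric
M-transform, ANOVA with Tukey's-b subsets, then the shared multivariate
stages plus Procrustes alignment and relative warps.

Both return a ``Report`` whose tables can be written to an output directory
as CSV/JSON together with a manifest (inputs, configuration hash, seed,
package version) so identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from trussmorph import __version__
from trussmorph.discrimination import (
    CentroidDistanceMatrix,
    DFAResult,
    PCAConfig,
    PCAResult,
    dfa_fit,
    dfa_loocv,
    mahalanobis_centroids,
    pca,
    upgma,
)
from trussmorph.errors import TrussMorphError, ValidationError
from trussmorph.landmark_io import SpecimenDataset, TraitTable
from trussmorph.screening import ScreeningConfig, anova_screen, tukey_b_subsets
from trussmorph.shape import gpa_align, relative_warps, species_consensus
from trussmorph.size_correction import (
    CorrectedTable,
    fit_allometric_slopes,
    m_transform,
    ratio_log_transform,
)
from trussmorph.truss import compute_distances, exclude_sl_edge, full_truss_scheme

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Options shared by both tracks; defaults reproduce the study settings
    (alpha 0.05, eigenvalue retention 0.7, equal priors, LOOCV on)."""

    alpha: float = 0.05
    pca_threshold: float = 0.7
    loocv: bool = True
    ridge: float | None = None
    rw_alpha: float = 0.0
    rw_uniform: bool = True
    sl_pair: tuple[int, int] = (1, 6)
    log_sl_mean_mode: str = "mean_sl"
    seed: int = 0
    strict: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Bundle of every stage's tables plus a reproducibility manifest."""

    track: str
    tables: dict[str, Any] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary: dict[str, Any] = {"track": self.track}
        for name, obj in self.tables.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv")
            elif hasattr(obj, "to_csv"):
                obj.to_csv(outdir / f"{name}.csv")
            elif isinstance(obj, str):
                (outdir / f"{name}.nwk").write_text(obj + "\n")
            else:
                summary[name] = obj
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))
        (outdir / "report.json").write_text(
            json.dumps(self.summary(), indent=2, default=str)
        )

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {"track": self.track}
        out.update(self.manifest.get("headline", {}))
        return out


def _stage(name: str, manifest: dict) -> "_StageTimer":
    return _StageTimer(name, manifest)


class _StageTimer:
    def __init__(self, name: str, manifest: dict):
        self.name = name
        self.manifest = manifest

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.manifest.setdefault("stages", {})[self.name] = round(dt, 4)
        if exc is not None:
            logger.error("stage %s failed after %.2fs: %s", self.name, dt, exc)
            if isinstance(exc, TrussMorphError) and not str(exc).startswith(f"[{self.name}]"):
                exc.args = (f"[{self.name}] {exc}",)
        else:
            logger.info("stage %s: done in %.2fs", self.name, dt)
        return False


def size_summary(sl: pd.Series, species: pd.Series) -> pd.DataFrame:
    """Per-species SL mean, SD and coefficient of variation (CV = 100·SD/mean)."""
    grouped = sl.groupby(species)
    out = pd.DataFrame(
        {"n": grouped.size(), "mean_sl": grouped.mean(), "sd_sl": grouped.std(ddof=1)}
    )
    out["cv_pct"] = 100.0 * out["sd_sl"] / out["mean_sl"]
    return out


def _multivariate_stages(
    corrected: CorrectedTable, config: PipelineConfig, manifest: dict, tables: dict
) -> dict[str, Any]:
    screen_cfg = ScreeningConfig(alpha=config.alpha)
    with _stage("anova", manifest):
        anova = anova_screen(corrected, screen_cfg)
        tables["anova"] = anova.table
    retained = anova.retained
    if not retained:
        raise ValidationError("no significant variables retained by ANOVA")
    sub = CorrectedTable(
        values=corrected.values[retained],
        species=corrected.species,
        provenance=corrected.provenance,
    )

    ridge = config.ridge
    n, k = len(sub.values), len(sub.groups)
    if ridge is None and len(retained) >= n - k:
        # more variables than within-group degrees of freedom: the pooled
        # covariance is singular, so fall back to the ridge flag
        ridge = 1e-8
        logger.warning(
            "pooled covariance singular (%d variables, %d within-group df); "
            "applying ridge %g", len(retained), n - k, ridge,
        )
        manifest["ridge_applied"] = ridge

    with _stage("pca", manifest):
        pca_res = pca(sub, PCAConfig(retention_threshold=config.pca_threshold))
        tables["pca_eigen"] = pd.DataFrame(
            {
                "eigenvalue": pca_res.eigenvalues,
                "variance_pct": pca_res.variance_pct,
                "cumulative_pct": pca_res.cumulative_pct,
            },
            index=pca_res.loadings.columns,
        )
        tables["pca_scores"] = pca_res.scores

    with _stage("dfa", manifest):
        dfa = dfa_fit(sub, ridge=ridge, loocv=config.loocv)
        tables["classification_original"] = dfa.classification_original
        if dfa.classification_loocv is not None:
            tables["classification_loocv"] = dfa.classification_loocv
        tables["canonical_coefficients"] = dfa.canonical_coefficients

    with _stage("mahalanobis", manifest):
        centroids = mahalanobis_centroids(sub, ridge=ridge)
        tables["mahalanobis"] = centroids

    with _stage("upgma", manifest):
        tree = upgma(centroids)
        tables["upgma_newick"] = tree.to_newick()

    return {
        "anova": anova,
        "pca": pca_res,
        "dfa": dfa,
        "centroids": centroids,
        "tree": tree,
        "subset": sub,
    }


def run_traditional(
    traits: TraitTable, config: PipelineConfig | None = None
) -> Report:
    """Traditional track: ratio/log correction then the multivariate stages."""
    config = config or PipelineConfig()
    report = Report(track="traditional")
    manifest = report.manifest
    manifest.update(
        {"config": asdict(config), "config_hash": config.config_hash(), "version": __version__}
    )
    tables = report.tables

    with _stage("size_summary", manifest):
        tables["size_summary"] = size_summary(traits.data["SL"], traits.species)

    with _stage("ratio_log", manifest):
        corrected = ratio_log_transform(traits)
        tables["corrected"] = corrected.values

    stages = _multivariate_stages(corrected, config, manifest, tables)

    manifest["headline"] = {
        "n_specimens": len(traits.data),
        "n_variables_analyzed": len(corrected.variables),
        "n_significant": stages["anova"].n_significant,
        "pca_retained": stages["pca"].retained,
        "pca_retained_variance_pct": round(stages["pca"].retained_variance_pct(), 2),
        "dfa_original_pct": round(stages["dfa"].classification_original.overall_pct, 1),
        "dfa_loocv_pct": (
            round(stages["dfa"].classification_loocv.overall_pct, 1)
            if stages["dfa"].classification_loocv
            else None
        ),
        "upgma_newick": tables["upgma_newick"],
    }
    return report


def run_truss(
    dataset: SpecimenDataset, config: PipelineConfig | None = None
) -> Report:
    """Truss track: distances, M-transform, screening, multivariate stages,
    then Procrustes alignment and relative warps."""
    config = config or PipelineConfig()
    if not dataset.configurations:
        raise ValidationError("truss track needs landmark configurations")
    report = Report(track="truss")
    manifest = report.manifest
    manifest.update(
        {"config": asdict(config), "config_hash": config.config_hash(), "version": __version__}
    )
    tables = report.tables
    empty = [g for g, n in dataset.group_sizes().items() if n == 0]
    if empty:
        raise ValidationError(f"empty species groups: {empty}")

    with _stage("truss_distances", manifest):
        scheme = full_truss_scheme(dataset.n_landmarks)
        distances = compute_distances(dataset.configurations, scheme, sl_pair=config.sl_pair)
        tables["distances"] = distances.values
        sl = distances.sl_values()

    with _stage("size_summary", manifest):
        tables["size_summary"] = size_summary(sl, distances.species)

    with _stage("sl_exclusion", manifest):
        analyzed = exclude_sl_edge(distances)

    with _stage("m_transform", manifest):
        model = fit_allometric_slopes(
            analyzed, sl_values=sl, log_sl_mean_mode=config.log_sl_mean_mode
        )
        corrected = m_transform(analyzed, model, sl_values=sl)
        tables["corrected"] = corrected.values
        tables["slopes"] = pd.Series(model.b, name="b").to_frame()

    screen_cfg = ScreeningConfig(alpha=config.alpha)
    with _stage("tukey_b", manifest):
        subsets = tukey_b_subsets(corrected, config=screen_cfg)
        tables["tukey_b_fully_separating"] = pd.DataFrame(
            {"fully_separating": pd.Series(subsets.fully_separating)}
        )

    stages = _multivariate_stages(corrected, config, manifest, tables)

    with _stage("gpa", manifest):
        fit = gpa_align(dataset.configurations)
        _, deviations = species_consensus(fit)
        tables["consensus"] = pd.DataFrame(fit.consensus, columns=["x", "y"])

    with _stage("relative_warps", manifest):
        rw = relative_warps(fit, alpha=config.rw_alpha, uniform_included=config.rw_uniform)
        tables["rw_scores"] = rw.warp_scores
        tables["rw_variance"] = pd.DataFrame(
            {"variance_pct": rw.variance_pct},
            index=list(rw.warp_scores.columns),
        )

    manifest["headline"] = {
        "n_specimens": len(dataset.configurations),
        "n_distances": scheme.n_edges,
        "n_variables_analyzed": len(corrected.variables),
        "n_significant": stages["anova"].n_significant,
        "n_fully_separating": subsets.n_fully_separating,
        "pca_retained": stages["pca"].retained,
        "pca_retained_variance_pct": round(stages["pca"].retained_variance_pct(), 2),
        "dfa_original_pct": round(stages["dfa"].classification_original.overall_pct, 1),
        "dfa_loocv_pct": (
            round(stages["dfa"].classification_loocv.overall_pct, 1)
            if stages["dfa"].classification_loocv
            else None
        ),
        "rw1_variance_pct": (
            round(float(rw.variance_pct[0]), 2) if len(rw.variance_pct) else None
        ),
        "upgma_newick": tables["upgma_newick"],
    }
    return report
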