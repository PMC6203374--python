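"""Synthetic multi-species morphometric datasets with known ground truth.

Each species is modeled by a mean 14-landmark body outline (unit centroid
size), isotropic landmark noise, a log-normal standard-length distribution,
a per-landmark allometric exponent, and integer meristic counts drawn as
rounded truncated Gaussians (a Poisson model cannot honor the near-zero
standard deviations real fin-ray counts show, e.g. a dorsal-fin-ray count
that is exactly 9 in every specimen of a species).

The default models emulate five small barbs (subfamily Barbinae): sample
sizes and standard-length distributions follow the published per-species
means and standard deviations, meristic means/SDs follow the published count
table, and the five mean shapes are hand-built outlines that differ at the
dorsal-fin and anal-fin landmarks (3, 4, 5 and 8), where real interspecific
shape variation concentrates in this group.

Allometry is realized radially: landmark ``l`` sits at distance
``r_l · s^{b_l}`` from the shape centroid, where ``s`` is the specimen's
size factor.  Distances between landmarks therefore grow with exponents that
are exact when both endpoints share ``b`` and approximate otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from trussmorph.errors import ConfigurationError
from trussmorph.landmark_io import LandmarkConfiguration, SpecimenDataset, TraitTable

#: 14-landmark base outline of a generic barb in lateral view, snout at left.
#: Landmark order: 1 snout tip, 2 nape, 3 dorsal-fin origin, 4 dorsal-fin end,
#: 5 dorsal caudal-membrane attachment, 6 posterior end of vertebral column,
#: 7 ventral caudal-membrane attachment, 8 anal-fin end, 9 anal-fin origin,
#: 10 pelvic-fin insertion, 11 pectoral-fin insertion, 12 operculum end,
#: 13 posterior eye, 14 anterior eye.
BASE_SHAPE = np.array(
    [
        [0.00, 0.50],
        [0.22, 0.72],
        [0.42, 0.82],
        [0.58, 0.78],
        [0.88, 0.62],
        [1.00, 0.50],
        [0.88, 0.38],
        [0.72, 0.30],
        [0.60, 0.28],
        [0.42, 0.22],
        [0.24, 0.30],
        [0.22, 0.45],
        [0.12, 0.55],
        [0.07, 0.56],
    ]
)

#: Species-specific displacements (before the separation multiplier) applied
#: to landmarks 3, 4, 5 and 8 (1-based) of the base outline.
_SHAPE_OFFSETS: dict[str, dict[int, tuple[float, float]]] = {
    "S. sarana": {3: (0.00, 0.06), 4: (0.02, 0.05), 5: (0.00, 0.03), 8: (0.01, -0.03)},
    "P. sophore": {3: (-0.02, -0.02), 4: (-0.02, -0.02), 5: (0.01, -0.01), 8: (-0.02, 0.02)},
    "P. chola": {3: (0.03, 0.00), 4: (0.03, 0.01), 5: (-0.02, 0.00), 8: (0.03, 0.00)},
    "P. ticto": {3: (0.00, -0.05), 4: (-0.03, -0.04), 5: (0.02, 0.02), 8: (0.00, -0.04)},
    "P. conchonius": {3: (-0.03, 0.04), 4: (0.01, -0.05), 5: (-0.01, -0.03), 8: (-0.03, -0.02)},
}

#: Published per-species standard-length mean and SD (cm) and truss-track
#: sample sizes for the five barbs.
_SL_STATS: dict[str, tuple[float, float, int]] = {
    "S. sarana": (16.82, 3.04, 18),
    "P. sophore": (7.13, 0.76, 20),
    "P. chola": (8.18, 0.32, 9),
    "P. ticto": (5.45, 0.32, 20),
    "P. conchonius": (5.75, 0.45, 11),
}

#: Published meristic means ± SD per species.  Codes: SLL lateral-series
#: scales, STR transverse-series scales, PDS pre-dorsal scales, CCS caudal
#: circumferential scales, DFR dorsal fin rays, PFR pectoral fin rays, PLFR
#: pelvic fin rays, AFR anal fin rays, CFR caudal fin rays, VCC vertebral
#: column count.
_MERISTICS: dict[str, dict[str, tuple[float, float]]] = {
    "S. sarana": {
        "SLL": (31.708, 1.083), "STR": (10.208, 0.388), "PDS": (10.958, 0.204),
        "CCS": (14.971, 1.018), "DFR": (12.208, 0.451), "PFR": (14.250, 0.532),
        "PLFR": (9.000, 0.000), "AFR": (9.125, 0.448), "CFR": (19.208, 0.415),
        "VCC": (32.333, 0.637),
    },
    "P. sophore": {
        "SLL": (24.000, 0.894), "STR": (8.000, 0.000), "PDS": (8.667, 0.516),
        "CCS": (12.000, 0.632), "DFR": (9.000, 0.000), "PFR": (15.000, 0.000),
        "PLFR": (8.000, 0.000), "AFR": (9.000, 0.000), "CFR": (19.000, 0.000),
        "VCC": (26.000, 0.000),
    },
    "P. chola": {
        "SLL": (26.417, 1.379), "STR": (9.167, 0.389), "PDS": (9.083, 0.793),
        "CCS": (12.167, 0.835), "DFR": (10.000, 0.000), "PFR": (14.833, 0.389),
        "PLFR": (7.333, 0.492), "AFR": (9.000, 0.000), "CFR": (19.000, 0.000),
        "VCC": (27.583, 0.793),
    },
    "P. ticto": {
        "SLL": (24.200, 0.894), "STR": (8.700, 0.571), "PDS": (10.500, 0.513),
        "CCS": (11.150, 0.366), "DFR": (9.000, 0.000), "PFR": (11.700, 0.470),
        "PLFR": (9.000, 0.000), "AFR": (6.000, 0.000), "CFR": (19.000, 0.000),
        "VCC": (25.450, 0.887),
    },
    "P. conchonius": {
        "SLL": (25.125, 0.991), "STR": (9.250, 0.463), "PDS": (8.875, 0.641),
        "CCS": (11.875, 0.354), "DFR": (11.000, 0.000), "PFR": (12.625, 0.744),
        "PLFR": (7.750, 0.463), "AFR": (9.000, 0.000), "CFR": (19.000, 0.000),
        "VCC": (25.000, 0.000),
    },
}

#: Landmark pairs (1-based) defining the derived traditional measurements.
TRAIT_EDGES: dict[str, tuple[int, int]] = {
    "SL": (1, 6),      # standard length
    "HL": (1, 12),     # head length
    "MBD": (3, 10),    # maximum body depth
    "PDL": (1, 3),     # pre-dorsal length
    "PVL": (1, 10),    # pre-ventral length
    "PAL": (1, 9),     # pre-anal length
    "DCPD": (5, 7),    # depth of caudal peduncle
    "LCPD": (9, 6),    # caudal peduncle length
    "ED": (13, 14),    # eye diameter
    "PROL": (1, 14),   # pre-orbital length
    "POOL": (12, 13),  # post-orbital length
}

#: Traits divided by head length rather than standard length downstream.
HEAD_TRAITS = ("ED", "PROL", "POOL")


def _unit_centroid_size(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


@dataclass
class SpeciesModel:
    """Generative model of one species' morphology."""

    label: str
    mean_shape: np.ndarray  # (14, 2), unit centroid size
    shape_sd: float = 0.01
    size_logmean: float = 1.0  # log10 SL (cm)
    size_logsd: float = 0.03
    allometric_b: float | np.ndarray = 1.0
    meristic_spec: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean_shape = _unit_centroid_size(np.asarray(self.mean_shape, dtype=float))
        if self.shape_sd < 0 or self.size_logsd < 0:
            raise ConfigurationError("noise SDs must be non-negative")

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]


@dataclass
class GeneratorConfig:
    species: list[SpeciesModel]
    n_per_species: list[int]
    seed: int = 0
    separation: float = 1.0

    def __post_init__(self) -> None:
        if len(self.species) != len(self.n_per_species):
            raise ConfigurationError(
                f"{len(self.species)} species but {len(self.n_per_species)} sample sizes"
            )
        if len(self.species) < 2:
            raise ConfigurationError("need at least 2 species")
        if any(n < 2 for n in self.n_per_species):
            raise ConfigurationError("every species needs n >= 2")


def default_barbinae_models(separation: float = 1.0, shape_sd: float = 0.01) -> list[SpeciesModel]:
    """Five-species models mirroring the published size and meristic tables.

    ``separation`` multiplies the between-species mean-shape offsets at
    landmarks 3, 4, 5 and 8 relative to the shared base outline.
    """
    models = []
    for label in _SL_STATS:
        mean_sl, sd_sl, _ = _SL_STATS[label]
        shape = BASE_SHAPE.copy()
        for lm, (dx, dy) in _SHAPE_OFFSETS[label].items():
            shape[lm - 1] += separation * np.array([dx, dy])
        # delta method: SD of log10 SL from the arithmetic mean and SD
        logsd = sd_sl / (mean_sl * np.log(10))
        models.append(
            SpeciesModel(
                label=label,
                mean_shape=shape,
                shape_sd=shape_sd,
                size_logmean=float(np.log10(mean_sl)),
                size_logsd=float(logsd),
                allometric_b=1.0,
                meristic_spec=dict(_MERISTICS[label]),
            )
        )
    return models


def default_n_per_species() -> list[int]:
    """Published truss-track sample sizes, in model order."""
    return [n for _, _, n in _SL_STATS.values()]


def generate(config: GeneratorConfig) -> SpecimenDataset:
    """Draw a full dataset: landmark configurations, derived traits, meristics.

    For each specimen a standard length is drawn from the species' log-normal,
    landmarks are placed radially at ``r_l · s^{b_l}`` from the shape centroid
    (``s`` scaled so the snout–vertebral-column edge equals SL under
    isometry), and isotropic Gaussian noise proportional to specimen size is
    added.  The same coordinates yield the traditional trait measurements, so
    both pipeline tracks see one consistent ground truth.
    """
    rng = np.random.default_rng(config.seed)
    configs: list[LandmarkConfiguration] = []
    trait_rows: list[dict] = []
    ids: list[str] = []
    species_labels: list[str] = []
    true_sl: list[float] = []

    for model, n in zip(config.species, config.n_per_species):
        shape = model.mean_shape  # unit centroid size, centered
        centered = shape - shape.mean(axis=0)
        radii = np.sqrt((centered**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            dirs = np.where(radii[:, None] > 0, centered / radii[:, None], 0.0)
        sl_pair = TRAIT_EDGES["SL"]
        d16 = float(np.linalg.norm(shape[sl_pair[0] - 1] - shape[sl_pair[1] - 1]))
        b = np.broadcast_to(np.asarray(model.allometric_b, dtype=float), (model.n_landmarks,))

        for i in range(n):
            sl = 10.0 ** rng.normal(model.size_logmean, model.size_logsd)
            s = sl / d16  # snout–vertebra edge equals SL under isometry
            pts = dirs * (radii * s**b)[:, None]
            pts = pts + rng.normal(0.0, model.shape_sd * s, size=pts.shape)
            sid = f"{model.label.replace(' ', '_').replace('.', '')}_{i:03d}"
            configs.append(
                LandmarkConfiguration(specimen_id=sid, species=model.label, points=pts)
            )
            row: dict[str, float] = {}
            for trait, (a_lm, b_lm) in TRAIT_EDGES.items():
                row[trait] = float(np.linalg.norm(pts[a_lm - 1] - pts[b_lm - 1]))
            for code, (mean, sd) in model.meristic_spec.items():
                draw = rng.normal(mean, sd) if sd > 0 else mean
                row[code] = float(max(0, round(draw)))
            trait_rows.append(row)
            ids.append(sid)
            species_labels.append(model.label)
            true_sl.append(sl)

    data = pd.DataFrame(trait_rows, index=pd.Index(ids, name="specimen_id"))
    roles = {t: "morphometric" for t in TRAIT_EDGES}
    if config.species[0].meristic_spec:
        roles.update({c: "meristic" for c in config.species[0].meristic_spec})
    traits = TraitTable(
        data=data,
        species=pd.Series(species_labels, index=data.index, name="species"),
        roles=roles,
    )
    dataset = SpecimenDataset(
        configurations=configs,
        traits=traits,
        groups=[m.label for m in config.species],
    )
    # generator-only ground truth: the drawn (noise-free) standard lengths,
    # for parameter-recovery checks against the fitted allometric slopes
    dataset.ground_truth = {"sl": pd.Series(true_sl, index=data.index, name="true_sl")}
    return dataset
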