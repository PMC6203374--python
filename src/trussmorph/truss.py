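"""Truss-network construction: all pairwise inter-landmark distances.

A full truss over ``k`` landmarks interconnects every pair, yielding
``k (k-1) / 2`` distance variables — 91 for the 14-landmark scheme used for
small cyprinids, where the snout-tip-to-vertebral-column-end edge (landmarks
1–6) is the standard length (SL).  SL serves as the basis of allometric size
correction and is therefore excluded from the analyzed variable set, leaving
90 characters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from trussmorph.errors import ConfigurationError, DomainError, ValidationError
from trussmorph.landmark_io import LandmarkConfiguration

#: Default landmark pair measuring standard length (1-based): snout tip to
#: posterior end of the vertebral column.
DEFAULT_SL_PAIR = (1, 6)


@dataclass(frozen=True)
class TrussScheme:
    """An ordered set of inter-landmark edges with ``Li-Lj`` labels."""

    landmark_count: int
    edges: tuple[tuple[int, int], ...]  # 1-based, i < j, lexicographic
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.edges)) != len(self.edges):
            raise ValidationError("duplicate edges in truss scheme")
        for i, j in self.edges:
            if not (1 <= i < j <= self.landmark_count):
                raise ValidationError(f"edge ({i}, {j}) out of range or unordered")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class DistanceTable:
    """Per-specimen truss distances (specimens × edges).

    ``values`` is indexed by specimen id with edge labels as columns;
    ``species`` is aligned to the same index.  ``sl_edge`` names the column
    holding standard length.
    """

    values: pd.DataFrame
    species: pd.Series
    sl_edge: str | None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("negative distance in table")

    @property
    def edge_labels(self) -> list[str]:
        return list(self.values.columns)

    def sl_values(self) -> pd.Series:
        if self.sl_edge is None or self.sl_edge not in self.values.columns:
            raise ConfigurationError("no SL edge present in this table")
        return self.values[self.sl_edge]

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, index_label="specimen_id")

    @classmethod
    def from_csv(cls, path: str | Path, sl_edge: str | None = None) -> "DistanceTable":
        df = pd.read_csv(path, index_col="specimen_id")
        species = df.pop("species")
        return cls(values=df, species=species, sl_edge=sl_edge)


def edge_label(i: int, j: int) -> str:
    return f"L{i}-L{j}"


def full_truss_scheme(landmark_count: int) -> TrussScheme:
    """All unordered landmark pairs, lexicographically ordered.

    >>> full_truss_scheme(14).n_edges
    91
    """
    if landmark_count < 2:
        raise DomainError(f"need at least 2 landmarks, got {landmark_count}")
    edges = tuple(combinations(range(1, landmark_count + 1), 2))
    labels = tuple(edge_label(i, j) for i, j in edges)
    return TrussScheme(landmark_count=landmark_count, edges=edges, labels=labels)


def compute_distances(
    configs: Sequence[LandmarkConfiguration],
    scheme: TrussScheme,
    sl_pair: tuple[int, int] | None = DEFAULT_SL_PAIR,
) -> DistanceTable:
    """Euclidean distance for every scheme edge of every specimen."""
    for c in configs:
        if c.n_landmarks != scheme.landmark_count:
            raise ValidationError(
                f"specimen {c.specimen_id!r} has {c.n_landmarks} landmarks, "
                f"scheme expects {scheme.landmark_count}"
            )
    ii = np.array([i - 1 for i, _ in scheme.edges])
    jj = np.array([j - 1 for _, j in scheme.edges])
    rows = np.empty((len(configs), scheme.n_edges))
    for r, c in enumerate(configs):
        diff = c.points[ii] - c.points[jj]
        rows[r] = np.hypot(diff[:, 0], diff[:, 1])
    index = pd.Index([c.specimen_id for c in configs], name="specimen_id")
    values = pd.DataFrame(rows, index=index, columns=list(scheme.labels))
    species = pd.Series([c.species for c in configs], index=index, name="species")
    sl_label = None
    if sl_pair is not None:
        lab = edge_label(min(sl_pair), max(sl_pair))
        if lab in values.columns:
            sl_label = lab
    return DistanceTable(values=values, species=species, sl_edge=sl_label)


def exclude_sl_edge(table: DistanceTable) -> DistanceTable:
    """Drop the standard-length edge before analysis (91 → 90 variables).

    Calling this on a table whose SL edge was already removed is an error, so
    the exclusion cannot silently drop an unrelated column twice.
    """
    if table.sl_edge is None:
        raise ConfigurationError("table has no designated SL edge")
    if table.sl_edge not in table.values.columns:
        raise ConfigurationError(
            f"SL edge {table.sl_edge!r} already excluded from this table"
        )
    values = table.values.drop(columns=[table.sl_edge])
    return DistanceTable(values=values, species=table.species, sl_edge=table.sl_edge)
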