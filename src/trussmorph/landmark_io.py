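"""Reading and writing landmark files (TPS dialect) and specimen trait tables.

The TPS dialect handled here is the plain-text format emitted by the common
landmark-digitizing tools: each record starts with an ``LM=<k>`` line, is
followed by ``k`` whitespace-separated ``x y`` coordinate lines, and may carry
optional ``ID=``, ``IMAGE=`` and ``SCALE=`` key lines.  Unknown ``KEY=value``
lines are tolerated with a logged warning, because digitizers emit several
optional keys and strict parsing would reject real files.

Coordinates are used exactly as stored (no y-axis flip): every downstream
quantity — inter-landmark distances and Procrustes shape coordinates — is
invariant to axis orientation.  When a ``SCALE=`` factor is present the
coordinates are converted to physical units on read; otherwise they remain in
pixel units and a warning is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trussmorph.errors import ConfigurationError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"LM", "ID", "IMAGE", "SCALE"}


@dataclass
class LandmarkConfiguration:
    """One specimen's digitized landmarks.

    Parameters
    ----------
    specimen_id:
        Unique specimen identifier (from ``ID=``, falling back to ``IMAGE=``,
        falling back to the record index).
    species:
        Species (group) label; may be empty until assigned by a dataset.
    points:
        ``(k, 2)`` float array of landmark coordinates, in physical units if a
        scale factor was applied, else in pixels.
    scale:
        Units-per-pixel factor applied on read, or ``None``.
    """

    specimen_id: str
    species: str
    points: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: points must be a (k, 2) array, "
                f"got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: non-finite coordinate"
            )

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    def centroid_size(self) -> float:
        """Square root of summed squared deviations from the centroid."""
        centered = self.points - self.points.mean(axis=0)
        return float(np.sqrt((centered**2).sum()))


@dataclass
class TraitTable:
    """Named morphometric/meristic variables per specimen.

    ``data`` is indexed by specimen id; ``species`` is aligned to the same
    index.  ``roles`` maps each variable to ``"morphometric"`` (a length) or
    ``"meristic"`` (a non-negative integer count).
    """

    data: pd.DataFrame
    species: pd.Series
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.species.isna().any():
            missing = list(self.species.index[self.species.isna()])
            raise ValidationError(f"missing species label for specimens {missing}")
        if self.data.columns.duplicated().any():
            dups = list(self.data.columns[self.data.columns.duplicated()])
            raise ValidationError(f"duplicate variable names: {dups}")
        unknown = set(self.roles) - set(self.data.columns)
        if unknown:
            raise ConfigurationError(f"roles given for absent variables: {sorted(unknown)}")
        for name, role in self.roles.items():
            if role not in ("morphometric", "meristic"):
                raise ConfigurationError(f"unknown role {role!r} for variable {name!r}")
            if role == "meristic":
                col = self.data[name]
                if (col < 0).any() or not np.allclose(col, np.round(col)):
                    raise ValidationError(
                        f"meristic variable {name!r} contains non-integer or negative values"
                    )

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s, None)
        return list(seen)

    def group_sizes(self) -> pd.Series:
        return self.species.value_counts().reindex(self.groups)


@dataclass
class SpecimenDataset:
    """A validated multi-species dataset of landmark configurations and/or traits."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)
    traits: TraitTable | None = None
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.configurations and self.traits is None:
            raise ValidationError("dataset needs configurations, traits, or both")
        if not self.groups:
            labels: dict[str, None] = {}
            for c in self.configurations:
                if c.species:
                    labels.setdefault(c.species, None)
            if self.traits is not None:
                for s in self.traits.species:
                    labels.setdefault(s, None)
            self.groups = list(labels)
        if self.configurations:
            counts = {c.n_landmarks for c in self.configurations}
            if len(counts) > 1:
                raise ValidationError(f"inconsistent landmark counts: {sorted(counts)}")

    @property
    def n_landmarks(self) -> int | None:
        return self.configurations[0].n_landmarks if self.configurations else None

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in self.groups}
        if self.configurations:
            for c in self.configurations:
                sizes[c.species] = sizes.get(c.species, 0) + 1
        elif self.traits is not None:
            for g, n in self.traits.species.value_counts().items():
                sizes[g] = int(n)
        return sizes

    def summary(self) -> dict:
        """JSON-serializable overview used by pipeline manifests."""
        return {
            "n_specimens": len(self.configurations)
            if self.configurations
            else (0 if self.traits is None else len(self.traits.data)),
            "n_landmarks": self.n_landmarks,
            "groups": self.groups,
            "group_sizes": self.group_sizes(),
            "n_trait_variables": None if self.traits is None else len(self.traits.variables),
        }


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into configurations.

    Raises
    ------
    ParseError
        If a record's coordinate lines disagree with its declared ``LM=``
        count, or a coordinate is non-numeric (the message carries the line
        number).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []

    record_start = None
    declared = 0
    coords: list[tuple[float, float]] = []
    meta: dict[str, str] = {}
    any_scale = False

    def flush(record_index: int, end_line: int) -> None:
        nonlocal any_scale
        if record_start is None:
            return
        if len(coords) != declared:
            raise ParseError(
                f"{path.name}: record starting at line {record_start} declares "
                f"LM={declared} but has {len(coords)} coordinate lines"
            )
        pts = np.asarray(coords, dtype=float)
        scale = None
        if "SCALE" in meta:
            try:
                scale = float(meta["SCALE"])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: record at line {record_start}: bad SCALE "
                    f"{meta['SCALE']!r}"
                ) from exc
            pts = pts * scale
            any_scale = True
        specimen_id = meta.get("ID") or meta.get("IMAGE") or str(record_index)
        configs.append(
            LandmarkConfiguration(specimen_id=specimen_id, species="", points=pts, scale=scale)
        )

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        key_val = line.split("=", 1) if "=" in line else None
        if key_val is not None and key_val[0].strip().upper() == "LM":
            flush(len(configs), lineno)
            record_start = lineno
            try:
                declared = int(key_val[1])
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: bad LM count {key_val[1]!r}") from exc
            coords = []
            meta = {}
        elif key_val is not None and not _looks_like_coords(line):
            if record_start is None:
                raise ParseError(f"{path.name}:{lineno}: data before first LM= record")
            key = key_val[0].strip().upper()
            if key not in _KNOWN_KEYS:
                logger.warning("%s:%d: ignoring unknown key %r", path.name, lineno, key)
            meta[key] = key_val[1].strip()
        else:
            if record_start is None:
                raise ParseError(f"{path.name}:{lineno}: coordinates before first LM= record")
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(
                    f"{path.name}:{lineno}: expected 'x y' pair, got {line!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric coordinate {line!r}") from exc
    flush(len(configs), len(lines) + 1)

    if configs and not any_scale:
        logger.warning("%s: no SCALE= records; coordinates remain in pixel units", path.name)
    return configs


def _looks_like_coords(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0])
        float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(
    configs: Iterable[LandmarkConfiguration], path: str | Path, precision: int = 6
) -> None:
    """Write configurations as TPS records (coordinates in stored units).

    A ``SCALE=`` line is intentionally not re-emitted: stored coordinates are
    already in physical units, so round-tripping through ``read_tps`` returns
    identical points.
    """
    path = Path(path)
    out: list[str] = []
    for c in configs:
        out.append(f"LM={c.n_landmarks}")
        for x, y in c.points:
            out.append(f"{x:.{precision}f} {y:.{precision}f}")
        out.append(f"ID={c.specimen_id}")
    path.write_text("\n".join(out) + "\n")


def read_trait_table(
    path: str | Path,
    species_column: str,
    variable_roles: Mapping[str, str],
    id_column: str | None = None,
) -> TraitTable:
    """Load a CSV/XLSX trait table and type its columns.

    Rows containing any unparseable value for a declared variable (e.g. a
    non-integer in a meristic column) are rejected; the rejection report is
    logged and attached to the raised/returned object.  Only columns listed in
    ``variable_roles`` are kept as variables.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]

    if species_column not in df.columns:
        raise ConfigurationError(
            f"species column {species_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)})"
        )
    missing_vars = [v for v in variable_roles if v not in df.columns]
    if missing_vars:
        raise ConfigurationError(f"variables absent from {path.name}: {missing_vars}")

    if id_column is None:
        candidates = [c for c in df.columns if c.lower() in ("id", "specimen", "specimen_id")]
        id_column = candidates[0] if candidates else None
    if id_column is not None:
        ids = df[id_column].astype(str)
    else:
        ids = pd.Series([str(i) for i in range(len(df))], index=df.index)
    if ids.duplicated().any():
        raise ValidationError(f"duplicate specimen ids: {sorted(ids[ids.duplicated()])}")

    species = df[species_column].astype(str)
    rejected: list[tuple[str, str]] = []
    values: dict[str, pd.Series] = {}
    bad_rows: set = set()
    for name, role in variable_roles.items():
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.isna() & df[name].notna()
        if role == "meristic":
            noninteger = col.notna() & ((col < 0) | (col != np.round(col)))
            bad = bad | noninteger
        bad = bad | df[name].isna()
        for i in df.index[bad]:
            rejected.append((str(ids[i]), f"{name}={df[name][i]!r} not a valid {role} value"))
            bad_rows.add(i)
        values[name] = col

    if rejected:
        for sid, reason in rejected:
            logger.warning("rejected specimen %s: %s", sid, reason)
    keep = df.index.difference(bad_rows)
    if len(keep) == 0:
        raise ValidationError(f"{path.name}: every row rejected ({rejected})")

    data = pd.DataFrame({k: v[keep] for k, v in values.items()})
    data.index = pd.Index(ids[keep], name="specimen_id")
    table = TraitTable(
        data=data,
        species=pd.Series(species[keep].values, index=data.index, name="species"),
        roles=dict(variable_roles),
    )
    table.rejected = rejected  # type: ignore[attr-defined]
    return table
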