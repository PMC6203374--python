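"""Body-size correction of measurement variables.

Two routes are provided:

``ratio_log`` (traditional track)
    Each morphometric variable is divided by its designated denominator —
    standard length (SL) for body measurements, head length (HL) for head
    measurements — and then log10-transformed.  Meristic counts are never
    divided (counts do not change with body size); they pass through
    log10-transformed only.

``m_transform`` (truss track)
    The allometric adjustment

        M_trans = log10 M − b · (log10 SL − log10 SL_mean)

    where ``M`` is the raw measurement, ``b`` the pooled within-group slope of
    log10 M on log10 SL, ``SL`` the specimen's standard length and ``SL_mean``
    the overall mean standard length.  With a correctly fitted ``b`` the
    corrected variable carries no residual within-group correlation with body
    size.

The within-group slope is pooled: one ``b`` per variable, estimated by least
squares after centering both log SL and log M by their group means, so that
corrected values remain comparable across species.  A per-group-slope variant
exists behind a flag for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from trussmorph.errors import ConfigurationError, ValidationError
from trussmorph.landmark_io import TraitTable
from trussmorph.truss import DistanceTable


@dataclass
class SizeCorrectionModel:
    """Fitted size-correction parameters.

    ``b`` maps variable name → allometric slope (dimensionless).  ``sl_mean``
    is the overall arithmetic mean standard length; its log enters the
    adjustment.  ``log_sl_mean_mode`` selects whether ``log SL_mean`` is
    ``log10(mean(SL))`` (default, matching the plain reading of "overall mean
    of the standard length") or ``mean(log10(SL))``.
    """

    method: str  # "ratio_log" | "m_transform"
    b: dict[str, float] = field(default_factory=dict)
    sl_mean: float = float("nan")
    denominator_map: dict[str, str] = field(default_factory=dict)
    log_base: int = 10
    log_sl_mean_mode: str = "mean_sl"  # or "mean_log_sl"
    per_group_b: dict[str, dict[str, float]] | None = None
    log_sl_mean: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "b": self.b,
            "sl_mean": self.sl_mean,
            "log_sl_mean": self.log_sl_mean,
            "log_sl_mean_mode": self.log_sl_mean_mode,
            "denominator_map": self.denominator_map,
            "log_base": self.log_base,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SizeCorrectionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            method=d["method"],
            b=d.get("b", {}),
            sl_mean=d.get("sl_mean", float("nan")),
            denominator_map=d.get("denominator_map", {}),
            log_base=d.get("log_base", 10),
            log_sl_mean_mode=d.get("log_sl_mean_mode", "mean_sl"),
            log_sl_mean=d.get("log_sl_mean", float("nan")),
        )


@dataclass
class CorrectedTable:
    """Size-corrected variables (log10 units) with their provenance."""

    values: pd.DataFrame
    species: pd.Series
    provenance: SizeCorrectionModel

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = list(self.values.columns[self.values.isna().any()])
            raise ValidationError(f"missing corrected values in {bad}")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s, None)
        return list(seen)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "species", self.species)
        out.to_csv(path, index_label="specimen_id")


#: Head-region variables divided by head length in the traditional track;
#: every other morphometric variable is divided by standard length.
DEFAULT_HL_VARIABLES = ("ED", "PROL", "POOL", "IOD", "IND", "MHW", "HDE", "HDN")


def default_denominator_map(variables: list[str], roles: Mapping[str, str]) -> dict[str, str]:
    """SL for body measurements, HL for the eight head measurements."""
    out: dict[str, str] = {}
    for v in variables:
        if roles.get(v) != "morphometric" or v in ("SL", "HL"):
            continue
        out[v] = "HL" if v in DEFAULT_HL_VARIABLES else "SL"
    return out


def ratio_log_transform(
    traits: TraitTable,
    denominator_map: Mapping[str, str] | None = None,
) -> CorrectedTable:
    """Divide morphometrics by SL or HL, then log10; meristics log10 only.

    SL is dropped from the output (it is the size proxy, not a shape
    variable).  HL is retained as a variable divided by SL, matching the
    convention of treating head length as one of the body measurements.
    Variables that are constant after transformation are flagged via the
    returned table's ``zero_variance`` attribute.
    """
    if "SL" not in traits.data.columns:
        raise ConfigurationError("trait table has no SL column")
    sl = traits.data["SL"]
    if (sl <= 0).any():
        bad = list(traits.data.index[sl <= 0])
        raise ValidationError(f"nonpositive SL for specimens {bad}")

    if denominator_map is None:
        denominator_map = default_denominator_map(traits.variables, traits.roles)
    needs_hl = any(d == "HL" for d in denominator_map.values())
    if needs_hl and "HL" not in traits.data.columns:
        raise ConfigurationError("denominator map uses HL but table has no HL column")
    if needs_hl:
        hl = traits.data["HL"]
        if (hl <= 0).any():
            bad = list(traits.data.index[hl <= 0])
            raise ValidationError(f"nonpositive HL for specimens {bad}")

    cols: dict[str, pd.Series] = {}
    for name in traits.variables:
        if name == "SL":
            continue
        role = traits.roles.get(name, "morphometric")
        if role == "meristic":
            col = traits.data[name].astype(float)
            if (col <= 0).any():
                raise ValidationError(f"meristic {name!r} has zero count; log undefined")
            cols[name] = np.log10(col)
        else:
            denom_name = denominator_map.get(name, "SL")
            denom = traits.data[denom_name]
            ratio = traits.data[name] / denom
            if (ratio <= 0).any():
                bad = list(traits.data.index[ratio <= 0])
                raise ValidationError(f"nonpositive ratio for {name!r}, specimens {bad}")
            cols[name] = np.log10(ratio)

    values = pd.DataFrame(cols, index=traits.data.index)
    model = SizeCorrectionModel(
        method="ratio_log",
        sl_mean=float(sl.mean()),
        denominator_map=dict(denominator_map),
    )
    table = CorrectedTable(values=values, species=traits.species.copy(), provenance=model)
    table.zero_variance = [c for c in values.columns if values[c].std() == 0]  # type: ignore[attr-defined]
    return table


def _pooled_within_group_slope(
    log_m: pd.DataFrame, log_sl: pd.Series, species: pd.Series
) -> pd.Series:
    """Least-squares slope of group-mean-centered log M on centered log SL."""
    x = log_sl - log_sl.groupby(species).transform("mean")
    y = log_m.sub(log_m.groupby(species).transform("mean"))
    sxx = float((x**2).sum())
    if sxx == 0:
        raise ValidationError("zero within-group variance of log SL; slopes undefined")
    return y.mul(x, axis=0).sum() / sxx


def fit_allometric_slopes(
    distances: DistanceTable,
    sl_values: pd.Series | None = None,
    log_sl_mean_mode: str = "mean_sl",
    per_group: bool = False,
) -> SizeCorrectionModel:
    """Fit the allometric slope ``b`` per variable and the overall SL mean.

    ``sl_values`` defaults to the table's designated SL edge.  Every group
    with at least two specimens contributes to the pooled slope.
    """
    if sl_values is None:
        sl_values = distances.sl_values()
    sl_values = sl_values.reindex(distances.values.index)
    if sl_values.isna().any():
        raise ValidationError("SL missing for some specimens")
    if (sl_values <= 0).any():
        raise ValidationError("nonpositive SL; log undefined")
    if len(distances.values) < 3:
        raise ValidationError("need at least 3 specimens to fit slopes")
    if (distances.values.values <= 0).any():
        bad = list(distances.values.columns[(distances.values <= 0).any()])
        raise ValidationError(f"nonpositive distances in {bad}; log undefined")

    work = distances.values
    if distances.sl_edge is not None and distances.sl_edge in work.columns:
        work = work.drop(columns=[distances.sl_edge])

    log_m = np.log10(work)
    log_sl = np.log10(sl_values)
    b = _pooled_within_group_slope(log_m, log_sl, distances.species)

    per_group_b = None
    if per_group:
        per_group_b = {}
        for g, idx in distances.species.groupby(distances.species).groups.items():
            if len(idx) < 2:
                continue
            sub = _pooled_within_group_slope(
                log_m.loc[idx], log_sl.loc[idx], distances.species.loc[idx]
            )
            per_group_b[str(g)] = {k: float(v) for k, v in sub.items()}

    sl_mean = float(sl_values.mean())
    if log_sl_mean_mode == "mean_sl":
        log_sl_mean = float(np.log10(sl_mean))
    elif log_sl_mean_mode == "mean_log_sl":
        log_sl_mean = float(log_sl.mean())
    else:
        raise ConfigurationError(f"unknown log_sl_mean_mode {log_sl_mean_mode!r}")

    return SizeCorrectionModel(
        method="m_transform",
        b={k: float(v) for k, v in b.items()},
        sl_mean=sl_mean,
        log_sl_mean_mode=log_sl_mean_mode,
        log_sl_mean=log_sl_mean,
        per_group_b=per_group_b,
    )


def m_transform(
    distances: DistanceTable,
    model: SizeCorrectionModel,
    sl_values: pd.Series | None = None,
) -> CorrectedTable:
    """Apply ``M_trans = log10 M − b (log10 SL − log10 SL_mean)`` per variable."""
    if model.method != "m_transform":
        raise ConfigurationError(f"model method is {model.method!r}, expected 'm_transform'")
    if sl_values is None:
        sl_values = distances.sl_values()
    sl_values = sl_values.reindex(distances.values.index)

    work = distances.values
    if distances.sl_edge is not None and distances.sl_edge in work.columns:
        work = work.drop(columns=[distances.sl_edge])
    missing = [v for v in work.columns if v not in model.b]
    if missing:
        raise ConfigurationError(f"model has no slope for variables {missing}")
    if (work.values <= 0).any():
        bad = list(work.columns[(work <= 0).any()])
        raise ValidationError(f"nonpositive measurement in {bad}; log undefined")
    if (sl_values <= 0).any():
        raise ValidationError("nonpositive SL; log undefined")

    log_m = np.log10(work)
    log_sl = np.log10(sl_values)
    b = pd.Series({v: model.b[v] for v in work.columns})
    adj = np.outer(log_sl - model.log_sl_mean, b.values)
    values = log_m - pd.DataFrame(adj, index=work.index, columns=work.columns)
    return CorrectedTable(values=values, species=distances.species.copy(), provenance=model)
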