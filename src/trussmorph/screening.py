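"""Per-character ANOVA screening and Tukey's-b homogeneous subsets.

Each variable is screened with a classical fixed-effects one-way ANOVA across
species; characters with p below the significance level are retained for the
multivariate stages.  No correction for testing many characters is applied by
default (per-character raw p-values are reported, a Holm option exists).

Tukey's-b is a stepwise range test whose critical value for a span of ``r``
ordered means is the arithmetic mean of the Tukey HSD critical value (at the
full number of groups) and the Student–Newman–Keuls critical value (at span
``r``), both from the studentized range distribution.  Unbalanced designs use
the harmonic mean group size in the standard error, recorded in the output
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from trussmorph.errors import DomainError, ValidationError
from trussmorph.landmark_io import TraitTable
from trussmorph.size_correction import CorrectedTable


@dataclass
class ScreeningConfig:
    alpha: float = 0.05
    min_group_n: int = 2
    holm: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class AnovaResult:
    """Per-variable F, df, p and retention flags.

    ``table`` columns: F, df_between, df_within, p, significant, degenerate.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="variable")


@dataclass
class HomogeneousSubsets:
    """Per-variable homogeneous subsets from the post-hoc range test.

    ``subsets[var]`` is a list of species-label lists, each subset's groups
    ordered by ascending mean; ``fully_separating[var]`` is True when every
    subset is a singleton (the character alone distinguishes all species).
    """

    subsets: dict[str, list[list[str]]]
    fully_separating: dict[str, bool]
    harmonic_n: float
    alpha: float

    @property
    def n_fully_separating(self) -> int:
        return sum(self.fully_separating.values())

    def fully_separating_variables(self) -> list[str]:
        return [v for v, flag in self.fully_separating.items() if flag]


def _extract(table: CorrectedTable | TraitTable) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(table, CorrectedTable):
        return table.values, table.species
    return table.data.astype(float), table.species


def anova_screen(
    table: CorrectedTable | TraitTable, config: ScreeningConfig | None = None
) -> AnovaResult:
    """One-way ANOVA per variable across species groups.

    Zero-total-variance variables are reported as degenerate and not tested.
    """
    config = config or ScreeningConfig()
    data, species = _extract(table)
    counts = species.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 groups for ANOVA")
    small = counts[counts < config.min_group_n]
    if len(small):
        raise ValidationError(
            f"groups below min_group_n={config.min_group_n}: {dict(small)}"
        )

    groups = list(dict.fromkeys(species))
    n_total = len(data)
    k = len(groups)
    df_b, df_w = k - 1, n_total - k

    rows = []
    for var in data.columns:
        y = data[var]
        if float(y.var(ddof=0)) == 0.0:
            rows.append((var, np.nan, df_b, df_w, np.nan, False, True))
            continue
        samples = [y[species == g].values for g in groups]
        f_stat, p = stats.f_oneway(*samples)
        rows.append((var, float(f_stat), df_b, df_w, float(p), bool(p < config.alpha), False))

    out = pd.DataFrame(
        rows, columns=["variable", "F", "df_between", "df_within", "p", "significant", "degenerate"]
    ).set_index("variable")

    if config.holm:
        tested = out.index[~out["degenerate"]]
        p = out.loc[tested, "p"].values
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        out.loc[tested, "p_holm"] = adj
        out.loc[tested, "significant"] = adj < config.alpha

    return AnovaResult(table=out, alpha=config.alpha)


@lru_cache(maxsize=4096)
def _q_range(alpha: float, span: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, span, df))


def _tukey_b_critical(alpha: float, k: int, span: int, df: int) -> float:
    """Mean of the HSD (full k) and SNK (span r) studentized-range quantiles."""
    return 0.5 * (_q_range(alpha, k, df) + _q_range(alpha, span, df))


def tukey_b_subsets(
    table: CorrectedTable | TraitTable,
    anova: AnovaResult | None = None,
    config: ScreeningConfig | None = None,
) -> HomogeneousSubsets:
    """Construct homogeneous subsets of species per variable (Tukey's-b).

    For ordered group means, a maximal run of consecutive means whose range
    statistic falls below the Tukey's-b critical value at that span forms one
    subset; a variable whose subsets are all singletons separates every
    species on its own.
    """
    config = config or ScreeningConfig()
    data, species = _extract(table)
    groups = sorted(dict.fromkeys(species))
    k = len(groups)
    if k < 2:
        raise DomainError("need at least 2 groups for a range test")
    counts = species.value_counts()
    n_h = k / float(np.sum(1.0 / counts[groups].values))
    df_w = len(data) - k

    subsets: dict[str, list[list[str]]] = {}
    fully: dict[str, bool] = {}
    for var in data.columns:
        y = data[var]
        means = y.groupby(species).mean().reindex(groups)
        ssw = float(
            ((y - y.groupby(species).transform("mean")) ** 2).sum()
        )
        msw = ssw / df_w
        if msw == 0:
            # all groups internally constant; distinct means are trivially separated
            order = means.sort_values(kind="stable").index
            runs: list[list[str]] = []
            for g in order:
                if runs and means[runs[-1][-1]] == means[g]:
                    runs[-1].append(g)
                else:
                    runs.append([g])
            subsets[var] = runs
            fully[var] = all(len(r) == 1 for r in runs)
            continue
        se = np.sqrt(msw / n_h)
        order = list(means.sort_values(kind="stable").index)
        ordered_means = means[order].values

        found: list[list[str]] = []
        for i in range(k):
            j = i
            while j + 1 < k:
                span = j + 2 - i
                crit = _tukey_b_critical(config.alpha, k, span, df_w)
                if (ordered_means[j + 1] - ordered_means[i]) / se < crit:
                    j += 1
                else:
                    break
            found.append(order[i : j + 1])
        # drop subsets contained in another
        maximal = [
            s
            for idx, s in enumerate(found)
            if not any(set(s) < set(t) for t in found if t is not s)
        ]
        dedup: list[list[str]] = []
        for s in maximal:
            if s not in dedup:
                dedup.append(s)
        subsets[var] = dedup
        fully[var] = all(len(s) == 1 for s in dedup)

    return HomogeneousSubsets(
        subsets=subsets, fully_separating=fully, harmonic_n=float(n_h), alpha=config.alpha
    )


def sex_preflight(
    data: pd.DataFrame, sex: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Optional check that no variable differs between sexes (two-sample t per variable)."""
    levels = sorted(dict.fromkeys(sex))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 sex levels, got {levels}")
    a = data[sex == levels[0]]
    b = data[sex == levels[1]]
    t, p = stats.ttest_ind(a.values, b.values, axis=0)
    return pd.DataFrame(
        {"t": t, "p": p, "differs": p < alpha}, index=data.columns
    )
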