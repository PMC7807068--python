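"""Two-stage multimodal variable selection on random-survival-forest ranks.

Stage 1 screens SNPs and lifestyle factors *separately*: a forest is grown
on each group alone and only variables with distinctly low minimal depth
and positive permutation VIMP survive (operationalized as MD below the
group mean AND VIMP > 0 — a deterministic, scale-free reading of the
MD-vs-VIMP agreement plot).

Stage 2 combines the survivors in one forest and applies the multimodal
rule: order by minimal depth, compute the nested out-of-bag error curve
and per-variable drop errors, and keep the variables whose drop error
reaches a threshold delta (default 0.005 — the value that separates
variables which materially improve the nested c-index from those that do
not in the published example table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfigurationError
from .forest import (
    ForestConfig,
    NestedModelCurve,
    grow_forest,
    nested_error_curve,
    design_matrix,
)


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the two-stage selection rule.

    ``drop_error_threshold`` (delta) is the stage-2 inclusion bound on the
    drop error; ``vimp_threshold`` the stage-1 bound on VIMP (variables at
    or below it are never selected); ``min_stratum_events`` aborts
    per-stratum runs too small to support the procedure.
    """

    drop_error_threshold: float = 0.005
    vimp_threshold: float = 0.0
    min_stratum_events: int = 50

    def __post_init__(self) -> None:
        if self.drop_error_threshold <= 0:
            raise ConfigurationError("drop_error_threshold must be > 0")


@dataclass
class Stage2Result:
    """Output of the stage-2 multimodal selection."""

    selected: list[str]
    table: pd.DataFrame  # variable, minimal_depth, vimp, cindex, error, drop_error, selected
    curve: NestedModelCurve | None
    plot_data: pd.DataFrame  # md_rank vs vimp_rank per variable


def _group_variables(cohort: Cohort, variable_group: str) -> list[str]:
    if variable_group == "snps":
        return cohort.snps
    if variable_group == "lifestyles":
        # expand categoricals exactly as the forest design matrix does
        _, names = design_matrix(cohort)
        return [v for v in names if v not in cohort.snps]
    raise ConfigurationError(
        f"variable_group must be 'snps' or 'lifestyles', got {variable_group!r}"
    )


def stage1_select(
    cohort: Cohort,
    variable_group: str,
    forest_config: ForestConfig,
    selection_config: SelectionConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Screen one variable group with a forest grown on the group alone.

    Returns the selected variables and the full ranking table (variable,
    minimal depth, VIMP, ranks, selected flag) for audit.
    """
    sel = selection_config or SelectionConfig()
    variables = _group_variables(cohort, variable_group)
    if not variables:
        raise ConfigurationError(f"no variables in group {variable_group!r}")
    forest = grow_forest(cohort, forest_config, variables)
    md = forest.minimal_depth()
    vimp = forest.permutation_vimp()
    table = pd.DataFrame(
        {
            "variable": md.index,
            "minimal_depth": md.to_numpy(),
            "vimp": vimp.reindex(md.index).to_numpy(),
        }
    )
    table["md_rank"] = table["minimal_depth"].rank(method="first").astype(int)
    table["vimp_rank"] = (-table["vimp"]).rank(method="first").astype(int)
    table["selected"] = (table["minimal_depth"] < table["minimal_depth"].mean()) & (
        table["vimp"] > sel.vimp_threshold
    )
    table = table.sort_values("minimal_depth", ignore_index=True)
    return table.loc[table["selected"], "variable"].tolist(), table


def select_by_drop_error(
    variables: Sequence[str],
    drop_errors: Sequence[float],
    delta: float = 0.005,
) -> list[str]:
    """Variables whose nested-model drop error reaches the threshold.

    This is the final stage-2 rule; it applies equally to a freshly
    computed :class:`NestedModelCurve` and to a published drop-error
    column.
    """
    variables = list(variables)
    d = np.asarray(drop_errors, dtype=float)
    if len(variables) != len(d):
        raise ConfigurationError("variables and drop_errors lengths differ")
    return [v for v, dk in zip(variables, d) if dk >= delta]


def stage2_multimodal(
    cohort: Cohort,
    stage1_variables: Sequence[str],
    forest_config: ForestConfig,
    selection_config: SelectionConfig | None = None,
    nested_config: ForestConfig | None = None,
) -> Stage2Result:
    """Combined-forest multimodal selection of the final variable set.

    Fits one forest on all stage-1 survivors, orders them by minimal
    depth, computes the nested OOB error curve and drop errors, and keeps
    the variables with drop error >= delta.  ``nested_config`` optionally
    uses a lighter forest for the K nested refits.
    """
    sel = selection_config or SelectionConfig()
    stage1_variables = list(stage1_variables)
    if not stage1_variables:
        raise ConfigurationError("stage-1 variable set is empty")
    if len(stage1_variables) < 2:
        warnings.warn(
            "fewer than 2 stage-1 variables; stage 2 degenerates to the "
            "stage-1 output",
            stacklevel=2,
        )
        table = pd.DataFrame(
            {
                "variable": stage1_variables,
                "minimal_depth": np.nan,
                "vimp": np.nan,
                "cindex": np.nan,
                "error": np.nan,
                "drop_error": np.nan,
                "selected": True,
            }
        )
        return Stage2Result(stage1_variables, table, None, pd.DataFrame())

    forest = grow_forest(cohort, forest_config, stage1_variables)
    md = forest.minimal_depth().sort_values()
    vimp = forest.permutation_vimp()
    ordered = list(md.index)
    curve = nested_error_curve(
        cohort, ordered, nested_config or forest_config
    )
    table = curve.to_frame()
    table.insert(1, "minimal_depth", md.to_numpy())
    table.insert(2, "vimp", vimp.reindex(ordered).to_numpy())
    table["selected"] = table["drop_error"] >= sel.drop_error_threshold
    selected = table.loc[table["selected"], "variable"].tolist()
    plot_data = pd.DataFrame(
        {
            "variable": ordered,
            "md_rank": np.arange(1, len(ordered) + 1),
            "vimp_rank": (-vimp.reindex(ordered)).rank(method="first").astype(int).to_numpy(),
        }
    )
    return Stage2Result(selected, table, curve, plot_data)
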