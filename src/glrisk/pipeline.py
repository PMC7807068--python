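"""End-to-end orchestration: simulate/read -> QC -> select -> GMDR -> profile.

A :class:`PipelineConfig` fully determines a run: the input mode (simulate
a synthetic cohort or read the three cohort tables), the forest and
selection settings, the GMDR search settings, the risk-coding rules and
the master seed.  Stage seeds are derived deterministically from the
master seed and the stage name, so stages are independently reproducible
and the whole run is a pure function of its config.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    Cohort,
    ConfigurationError,
    DEFAULT_STRATA,
    qc_filter,
    read_cohort,
    stratify,
)
from .forest import ForestConfig
from .gmdr import (
    compute_scores,
    model_search,
    permutation_test,
    results_table,
    select_best,
)
from .profiles import (
    CoxFitError,
    LifestyleRule,
    RiskCoding,
    assign_risk_genotype,
    assign_risk_lifestyle,
    combine_gene_lifestyle,
    cox_fit,
    interaction_test,
    joint_effect_table,
    schoenfeld_check,
)
from .selection import SelectionConfig, stage1_select, stage2_multimodal
from .simulate import default_simspec, simulate_cohort, write_cohort

#: covariates used for adjustment in the profiling Cox models, minus any
#: variable currently under stratification or joint testing
DEFAULT_ADJUSTMENT = [
    "income_ge_35k",
    "bmi",
    "waist",
    "hip",
    "depressive_symptom",
    "cigarettes_per_day",
    "age_menopause",
    "oc_years",
    "ep_years",
    "protein_pct",
    "alcohol",
]

DEFAULT_LIFESTYLE_RULES = (
    LifestyleRule("alcohol", 18.0, "ge"),
    LifestyleRule("ep_years", 10.0, "ge"),
    LifestyleRule("oc_years", 5.0, "lt"),
    LifestyleRule("bmi", 30.0, "ge"),
)


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from (master seed, stage)."""
    h = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through JSON/YAML unchanged."""

    mode: str = "simulate"  # 'simulate' | 'files'
    n: int = 2000
    n_snps: int = 50
    with_effects: bool = True
    genotype_path: str | None = None
    covariate_path: str | None = None
    outcome_path: str | None = None
    strata: list[str] = field(default_factory=list)
    forest: dict = field(default_factory=dict)  # ForestConfig overrides
    nested_forest: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)  # SelectionConfig overrides
    gmdr_folds: int = 10
    gmdr_max_order: int = 2
    gmdr_n_perm: int = 199
    gmdr_pool_cap: int = 25
    adjustment: list[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))
    out_dir: str = "glrisk_out"
    seed: int = 0

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            yaml.safe_load(text)
            if str(path).endswith((".yml", ".yaml"))
            else json.loads(text)
        )
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    # -- resolved sub-configs ------------------------------------------
    def forest_config(self, stage: str) -> ForestConfig:
        kw = {"n_trees": 200, "vimp_reps": 2, **self.forest}
        kw["seed"] = derive_seed(self.seed, stage)
        return ForestConfig(**kw)

    def nested_forest_config(self, stage: str) -> ForestConfig:
        kw = {"n_trees": 100, "vimp_reps": 2, **self.forest, **self.nested_forest}
        kw["seed"] = derive_seed(self.seed, stage + ":nested")
        return ForestConfig(**kw)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(**self.selection)


def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.mode == "simulate":
        spec = default_simspec(
            n=config.n,
            n_snps=config.n_snps,
            seed=derive_seed(config.seed, "simulate"),
            with_effects=config.with_effects,
        )
        return simulate_cohort(spec, calibrate_to=537 / 10179)
    if config.mode == "files":
        if not (config.genotype_path and config.covariate_path and config.outcome_path):
            raise ConfigurationError("files mode needs the three table paths")
        return read_cohort(
            config.genotype_path, config.covariate_path, config.outcome_path
        )
    raise ConfigurationError(f"unknown mode {config.mode!r}")


def _select_and_gmdr(
    cohort: Cohort,
    config: PipelineConfig,
    label: str,
    out: Path,
    manifest: dict,
) -> list[str]:
    """Stage-1/stage-2 selection plus GMDR for one analysis group."""
    sel_cfg = config.selection_config()
    s1_snps, t_snps = stage1_select(
        cohort, "snps", config.forest_config(f"{label}:stage1_snps"), sel_cfg
    )
    s1_life, t_life = stage1_select(
        cohort,
        "lifestyles",
        config.forest_config(f"{label}:stage1_lifestyles"),
        sel_cfg,
    )
    t_snps.assign(group="snps").to_csv(
        out / f"{label}_stage1_snps.tsv", sep="\t", index=False
    )
    t_life.assign(group="lifestyles").to_csv(
        out / f"{label}_stage1_lifestyles.tsv", sep="\t", index=False
    )
    stage1_vars = s1_snps + s1_life
    if not stage1_vars:
        manifest["stages"][label] = {"selected": [], "note": "stage 1 empty"}
        return []
    result = stage2_multimodal(
        cohort,
        stage1_vars,
        config.forest_config(f"{label}:stage2"),
        sel_cfg,
        nested_config=config.nested_forest_config(f"{label}:stage2"),
    )
    result.table.to_csv(out / f"{label}_stage2.tsv", sep="\t", index=False)
    if len(result.plot_data):
        result.plot_data.to_csv(
            out / f"{label}_md_vimp_plot.tsv", sep="\t", index=False
        )
    selected = result.selected

    # GMDR over the selected SNPs (fall back to the best stage-1 SNPs when
    # the drop-error rule keeps fewer than two)
    snp_pool = [v for v in selected if v in cohort.snps]
    if len(snp_pool) < 2:
        snp_pool = s1_snps[: max(2, config.gmdr_max_order)]
    best_row = None
    if config.gmdr_max_order >= 1 and len(snp_pool) >= max(2, config.gmdr_max_order):
        adj = [c for c in config.adjustment if c in cohort.covariates.columns]
        scores = compute_scores(cohort.event, cohort.covariates[adj])
        geno = cohort.imputed_genotypes()
        results = model_search(
            scores,
            geno,
            snp_pool,
            max_order=min(config.gmdr_max_order, len(snp_pool)),
            folds=config.gmdr_folds,
            seed=derive_seed(config.seed, f"{label}:gmdr"),
            strat=cohort.event,
            pool_cap=config.gmdr_pool_cap,
        )
        for r in results:
            r.p_value = permutation_test(
                scores,
                geno[list(r.combo)].to_numpy(),
                n_perm=config.gmdr_n_perm,
                seed=derive_seed(config.seed, f"{label}:gmdr_perm:{r.order}"),
                folds=config.gmdr_folds,
                observed_tba=r.tba,
            )
        best = select_best(results)
        table = results_table(results, best)
        table.to_csv(out / f"{label}_gmdr.tsv", sep="\t", index=False)
        best_row = best.as_row() | {"significant": best.significant}
    manifest["stages"][label] = {
        "stage1_snps": s1_snps,
        "stage1_lifestyles": s1_life,
        "selected": selected,
        "gmdr_best": best_row,
    }
    return selected


def _risk_profile(
    cohort: Cohort,
    selected: list[str],
    config: PipelineConfig,
    out: Path,
    manifest: dict,
) -> None:
    """Combined risk-score profiling on the overall cohort."""
    snps = [v for v in selected if v in cohort.snps]
    if not snps:
        manifest["stages"]["profile"] = {"note": "no selected SNPs; skipped"}
        return
    geno = cohort.imputed_genotypes()
    # dominant carrier coding per selected SNP; risk side = the genotype
    # group with the higher crude event rate, a deterministic data-driven
    # stand-in for cumulative-incidence-curve inspection
    risk_sets: dict[str, tuple[float, ...]] = {}
    for snp in snps:
        carrier = geno[snp].to_numpy() >= 1
        rate_c = cohort.event[carrier].mean() if carrier.any() else 0.0
        rate_n = cohort.event[~carrier].mean() if (~carrier).any() else 0.0
        risk_sets[snp] = (1.0, 2.0) if rate_c >= rate_n else (0.0,)
    rules = tuple(
        r for r in DEFAULT_LIFESTYLE_RULES if r.variable in cohort.covariates.columns
    )
    coding = RiskCoding(
        snp_risk_sets=risk_sets,
        lifestyle_rules=rules,
        genotype_threshold=min(2, len(risk_sets)),
    )
    _, G = assign_risk_genotype(geno, coding)
    _, B = assign_risk_lifestyle(cohort.covariates, coding)
    C = combine_gene_lifestyle(G, (B >= 1).astype(int))
    strat_rule = LifestyleRule("alcohol", 18.0, "ge")
    stratifier = (
        strat_rule.risk_mask(cohort.covariates["alcohol"].to_numpy()).astype(int)
        if "alcohol" in cohort.covariates.columns
        else None
    )
    adj_cols = [
        c
        for c in config.adjustment
        if c in cohort.covariates.columns
        and c not in {"alcohol", "bmi", "oc_years", "ep_years"}
    ]
    adj = cohort.covariates[adj_cols]
    table = joint_effect_table(
        cohort.time_years, cohort.event, C, stratifier, adj
    )
    table.to_csv(out / "risk_profile.tsv", sep="\t", index=False)
    interaction = None
    if stratifier is not None and len(np.unique(G)) == 2:
        try:
            res = interaction_test(
                cohort.time_years, cohort.event, G, stratifier, adj
            )
            interaction = {
                k: v for k, v in res.items() if k != "hr_joint"
            } | {"hr_joint": res["hr_joint"]}
        except CoxFitError as exc:
            interaction = {"error": str(exc)}
    # forest-plot data file (estimate + CI per row)
    fp = table.loc[
        table["hr"].notna(), ["block", "level", "hr", "ci_low", "ci_high"]
    ]
    fp.to_csv(out / "forest_plot.tsv", sep="\t", index=False)
    # PH diagnostics on the adjusted combined-score model
    from .profiles import _dummies

    design = pd.concat([_dummies(C, "C_"), adj.reset_index(drop=True)], axis=1)
    try:
        fit = cox_fit(cohort.time_years, cohort.event, design)
        schoen, resid = schoenfeld_check(fit)
        schoen.to_csv(out / "schoenfeld.tsv", sep="\t", index=False)
        resid.to_csv(out / "schoenfeld_residuals.tsv", sep="\t", index=False)
    except CoxFitError as exc:
        schoen = None
        manifest.setdefault("warnings", []).append(f"profile PH check: {exc}")
    manifest["stages"]["profile"] = {
        "risk_sets": {k: list(v) for k, v in risk_sets.items()},
        "p_trend": float(table.attrs.get("p_trend", np.nan)),
        "interaction": interaction,
        "group_sizes": table.loc[table["block"] == "total", "n"].tolist(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write reports plus a manifest.

    Returns the manifest dict.  Reruns with the same config reproduce all
    numeric outputs exactly (the manifest's wall-clock differs).
    """
    t0 = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "seeds": {
            s: derive_seed(config.seed, s)
            for s in ("simulate", "overall:stage1_snps", "overall:stage2", "overall:gmdr")
        },
        "stages": {},
    }
    cohort = _load_cohort(config)
    if config.mode == "simulate":
        write_cohort(cohort, out / "cohort")
    cohort, qc_report = qc_filter(cohort)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {
        "n": int(cohort.n),
        "events": int(cohort.event.sum()),
        "snps_kept": len(cohort.snps),
        "snps_removed": len(qc_report),
    }

    selected = _select_and_gmdr(cohort, config, "overall", out, manifest)
    _risk_profile(cohort, selected, config, out, manifest)

    sel_cfg = config.selection_config()
    for name in config.strata:
        if name not in DEFAULT_STRATA:
            raise ConfigurationError(f"unknown stratum {name!r}")
        spec = DEFAULT_STRATA[name]
        low, high = stratify(cohort, spec, missing="drop")
        for side, sub in (("low", low), ("high", high)):
            label = f"{name}_{side}"
            if sub.event.sum() < sel_cfg.min_stratum_events:
                manifest["stages"][label] = {
                    "note": f"only {int(sub.event.sum())} events "
                    f"(< {sel_cfg.min_stratum_events}); aborted to avoid "
                    "overfitting a small subgroup"
                }
                continue
            _select_and_gmdr(sub, config, label, out, manifest)

    manifest["wall_clock_seconds"] = round(_time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
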