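"""Combined genotype-lifestyle risk scores and Cox joint-effect models.

SNPs are dichotomized into carrier/non-carrier of a *risk genotype* (e.g.
CT+TT for a dominant coding, or a homozygote for a recessive one), and
lifestyles into risk behaviors by a cutoff and direction (e.g. alcohol
>= 18 g/day, estrogen+progestin use >= 10 years, *short* past oral
contraceptive use < 5 years, BMI >= 30 kg/m^2).  The counts are binarized
per stratum rule (e.g. "all risk genotypes present") and added into the
combined score C in {0, 1, 2}: 0 = low risk on both axes, 1 = high risk
on one, 2 = high risk on both.

Hazard ratios come from Cox proportional-hazards regressions (Efron tie
handling by default, Breslow available), with Wald CIs, Benjamini-Hochberg
adjusted p-values within each report table, ordinal trend tests,
multiplicative (product-term) and additive (RERI) interaction measures,
and Schoenfeld-residual proportional-hazards diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ConfigurationError


class CoxFitError(Exception):
    """Cox model could not be estimated (non-convergence, empty level...)."""


# ----------------------------------------------------------------------
# Risk coding
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class LifestyleRule:
    """One risk-behavior dichotomy: variable, cutoff and risk direction.

    ``direction`` names the *risk* side: 'ge' (>= cutoff), 'gt', 'le',
    'lt'.  Short oral-contraceptive use is a risk behavior, so its rule is
    ('oc_years', 5, 'lt').
    """

    variable: str
    cutoff: float
    direction: str = "ge"

    def risk_mask(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        op = {
            "ge": v >= self.cutoff,
            "gt": v > self.cutoff,
            "le": v <= self.cutoff,
            "lt": v < self.cutoff,
        }
        if self.direction not in op:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        return op[self.direction]


@dataclass(frozen=True)
class RiskCoding:
    """Stratum-specific dichotomization of SNPs and lifestyles.

    ``snp_risk_sets`` maps SNP id -> dosage values counting as the risk
    genotype (e.g. (1, 2) for a dominant carrier coding, (2,) for a
    recessive homozygote).  ``genotype_threshold`` is the carrier count at
    which the binary G flips to 1 (default: all panel SNPs at risk).
    ``behavior_levels`` is 2 for a 0/1 behavioral coding and 3 for the
    0/1/2-or-more coding used in some strata.
    """

    snp_risk_sets: dict[str, tuple[float, ...]]
    lifestyle_rules: tuple[LifestyleRule, ...]
    genotype_threshold: int | None = None
    behavior_levels: int = 2

    @property
    def g_threshold(self) -> int:
        return (
            self.genotype_threshold
            if self.genotype_threshold is not None
            else len(self.snp_risk_sets)
        )


def assign_risk_genotype(
    genotypes: pd.DataFrame, coding: RiskCoding
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject risk-genotype count and binary G.

    ``count`` is the number of panel SNPs at which the subject carries the
    risk genotype; G = 1 when the count reaches the coding's threshold
    (default: every panel SNP).
    """
    missing = [s for s in coding.snp_risk_sets if s not in genotypes.columns]
    if missing:
        raise ConfigurationError(f"risk coding covers absent SNPs: {missing}")
    count = np.zeros(len(genotypes), dtype=int)
    for snp, risk_set in coding.snp_risk_sets.items():
        vals = genotypes[snp].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ConfigurationError(
                f"missing genotypes at {snp}; impute or drop before risk coding"
            )
        count += np.isin(vals, np.asarray(risk_set, dtype=float)).astype(int)
    G = (count >= coding.g_threshold).astype(int)
    return count, G


def assign_risk_lifestyle(
    covariates: pd.DataFrame, coding: RiskCoding
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject risk-behavior count and coded B.

    B is 0/1 (any risk behavior) when ``behavior_levels`` is 2, and
    0 / 1 / 2 ("2 or more risk behaviors") when it is 3.
    """
    count = np.zeros(len(covariates), dtype=int)
    for rule in coding.lifestyle_rules:
        if rule.variable not in covariates.columns:
            raise ConfigurationError(f"lifestyle rule on absent {rule.variable!r}")
        count += rule.risk_mask(covariates[rule.variable].to_numpy()).astype(int)
    if coding.behavior_levels == 2:
        B = (count >= 1).astype(int)
    elif coding.behavior_levels == 3:
        B = np.minimum(count, 2)
    else:
        raise ConfigurationError("behavior_levels must be 2 or 3")
    return count, B


def combine_gene_lifestyle(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Combined score C = G + B over binarized G and B: 0, 1 or 2."""
    G = np.asarray(G)
    B = np.asarray(B)
    for name, v in (("G", G), ("B", B)):
        if not np.isin(np.unique(v), [0, 1]).all():
            raise ConfigurationError(f"{name} must be binarized 0/1")
    return (G + B).astype(int)


# ----------------------------------------------------------------------
# Cox fitting
# ----------------------------------------------------------------------

@dataclass
class CoxResult:
    """Hazard ratios with CIs, raw and BH-adjusted p, and diagnostics."""

    summary: pd.DataFrame  # term, coef, se, hr, ci_low, ci_high, p, p_bh
    model: object
    data: pd.DataFrame
    duration_col: str = "time"
    event_col: str = "event"

    def hr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "hr"])


def cox_fit(
    time: np.ndarray,
    event: np.ndarray,
    design: pd.DataFrame,
    ties_method: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit by partial-likelihood maximization.

    ``design`` columns enter linearly.  Efron tie handling is the default;
    ``ties_method='breslow'`` uses the Breslow approximation (via the
    statsmodels PHReg backend).  Wald 95% CIs; HR = exp(coef).
    """
    event = np.asarray(event)
    if event.sum() < 2:
        raise CoxFitError("need at least 2 events")
    design = design.reset_index(drop=True).astype(float)
    if np.linalg.matrix_rank(np.c_[np.ones(len(design)), design.to_numpy()]) <= design.shape[1]:
        raise CoxFitError("design is rank deficient")
    df = pd.DataFrame({"time": np.asarray(time, dtype=float), "event": event})
    df = pd.concat([df, design], axis=1)
    if ties_method == "efron":
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:
            raise CoxFitError(f"Cox fit failed: {exc}") from exc
        s = cph.summary
        summary = pd.DataFrame(
            {
                "term": s.index,
                "coef": s["coef"].to_numpy(),
                "se": s["se(coef)"].to_numpy(),
                "hr": s["exp(coef)"].to_numpy(),
                "ci_low": s["exp(coef) lower 95%"].to_numpy(),
                "ci_high": s["exp(coef) upper 95%"].to_numpy(),
                "p": s["p"].to_numpy(),
            }
        )
        model = cph
    elif ties_method == "breslow":
        import statsmodels.duration.hazard_regression as hz

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = hz.PHReg(
                    df["time"], design, status=df["event"], ties="breslow"
                )
                res = mod.fit()
        except Exception as exc:
            raise CoxFitError(f"Cox fit failed: {exc}") from exc
        coef = res.params
        se = res.bse
        summary = pd.DataFrame(
            {
                "term": list(design.columns),
                "coef": coef,
                "se": se,
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - 1.959963984540054 * se),
                "ci_high": np.exp(coef + 1.959963984540054 * se),
                "p": 2 * stats.norm.sf(np.abs(coef / se)),
            }
        )
        model = res
    else:
        raise ConfigurationError(f"unknown ties_method {ties_method!r}")
    if not np.all(np.isfinite(summary["coef"])):
        raise CoxFitError("non-finite coefficients (monotone likelihood?)")
    summary["p_bh"] = bh_adjust(summary["p"].to_numpy())
    summary = summary.reset_index(drop=True)
    return CoxResult(summary=summary, model=model, data=df)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Joint-effect tables, trend, interaction, diagnostics
# ----------------------------------------------------------------------

def _dummies(values: np.ndarray, prefix: str) -> pd.DataFrame:
    """0/1 columns for each non-reference level of an ordinal factor."""
    levels = np.unique(values)
    return pd.DataFrame(
        {f"{prefix}{int(l)}": (values == l).astype(float) for l in levels[1:]}
    )


def trend_test(
    time: np.ndarray,
    event: np.ndarray,
    C: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Wald p for the linearly coded (0/1/2) score in the adjusted model."""
    C = np.asarray(C, dtype=float)
    if len(np.unique(C)) < 2:
        raise ConfigurationError("trend test needs >= 2 score levels")
    design = pd.DataFrame({"C_linear": C})
    if covariates is not None and len(covariates.columns):
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    res = cox_fit(time, event, design)
    return float(res.summary.set_index("term").loc["C_linear", "p"])


def joint_effect_table(
    time: np.ndarray,
    event: np.ndarray,
    C: np.ndarray,
    stratifier: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    score_name: str = "C",
) -> pd.DataFrame:
    """Per-score-level hazard ratios, overall and within stratifier levels.

    The reference is the lowest score level within each column block
    (HR = 1 by construction, blank CI).  Stratifier columns are produced
    by refitting the model within each stratum.  Cell counts and events
    are reported so empty cells are visible; BH adjustment is applied
    within the table as one family, and a trend p over the ordinal score
    is appended.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    C = np.asarray(C)
    blocks: list[tuple[str, np.ndarray]] = [("total", np.ones(len(C), dtype=bool))]
    if stratifier is not None:
        strat = np.asarray(stratifier)
        if len(np.unique(strat)) != 2:
            raise ConfigurationError("stratifier must be binary")
        blocks += [
            ("low_stratum", strat == np.unique(strat)[0]),
            ("high_stratum", strat == np.unique(strat)[1]),
        ]
    rows = []
    for block, mask in blocks:
        sub_t, sub_e, sub_c = time[mask], event[mask], C[mask]
        cov = (
            covariates.loc[mask].reset_index(drop=True)
            if covariates is not None
            else None
        )
        levels = np.unique(C)
        dummies = _dummies(sub_c, f"{score_name}_")
        design = dummies
        if cov is not None and len(cov.columns):
            design = pd.concat([dummies, cov], axis=1)
        fit = None
        if len(np.unique(sub_c)) >= 2 and sub_e.sum() >= 2:
            try:
                fit = cox_fit(sub_t, sub_e, design)
            except CoxFitError:
                fit = None
        for l in levels:
            at = sub_c == l
            row = {
                "block": block,
                "level": int(l),
                "n": int(at.sum()),
                "events": int(sub_e[at].sum()),
            }
            term = f"{score_name}_{int(l)}"
            if l == levels[0]:
                row.update(hr=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
            elif fit is not None and term in set(fit.summary["term"]) and at.sum() > 0:
                s = fit.summary.set_index("term").loc[term]
                row.update(
                    hr=s["hr"], ci_low=s["ci_low"], ci_high=s["ci_high"], p=s["p"]
                )
            else:
                row.update(hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)
    raw = table["p"].to_numpy()
    mask = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if mask.any():
        adj[mask] = bh_adjust(raw[mask])
    table["p_bh"] = adj
    table.attrs["p_trend"] = (
        trend_test(time, event, C, covariates)
        if len(np.unique(C)) >= 2
        else np.nan
    )
    return table


def interaction_test(
    time: np.ndarray,
    event: np.ndarray,
    G: np.ndarray,
    E: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Multiplicative and additive interaction of two binary factors.

    Multiplicative: hazard ratio and p of the G x E product term in the
    joint Cox model.  Additive: RERI = HR11 - HR10 - HR01 + 1 from the
    dummy-coded joint model, with a delta-method 95% CI.
    """
    G = np.asarray(G)
    E = np.asarray(E)
    for name, v in (("G", G), ("E", E)):
        if len(np.unique(v)) != 2:
            raise ConfigurationError(f"{name} must be binary and non-constant")
    cov = covariates.reset_index(drop=True) if covariates is not None else None

    # product-term model
    design = pd.DataFrame(
        {"G": G.astype(float), "E": E.astype(float), "GxE": (G * E).astype(float)}
    )
    if cov is not None and len(cov.columns):
        design = pd.concat([design, cov], axis=1)
    fit_prod = cox_fit(time, event, design)
    s = fit_prod.summary.set_index("term")

    # dummy-coded joint model for RERI
    g10 = ((G == 1) & (E == 0)).astype(float)
    g01 = ((G == 0) & (E == 1)).astype(float)
    g11 = ((G == 1) & (E == 1)).astype(float)
    for name, col in (("G=1,E=0", g10), ("G=0,E=1", g01), ("G=1,E=1", g11)):
        if col.sum() == 0:
            raise CoxFitError(f"inestimable cell {name}: no subjects")
    design2 = pd.DataFrame({"g10": g10, "g01": g01, "g11": g11})
    if cov is not None and len(cov.columns):
        design2 = pd.concat([design2, cov], axis=1)
    fit_joint = cox_fit(time, event, design2)
    idx = [list(fit_joint.summary["term"]).index(t) for t in ("g10", "g01", "g11")]
    beta = fit_joint.summary["coef"].to_numpy()[idx]
    if hasattr(fit_joint.model, "variance_matrix_"):
        V = np.asarray(fit_joint.model.variance_matrix_)[np.ix_(idx, idx)]
    else:  # statsmodels backend
        V = fit_joint.model.cov_params().to_numpy()[np.ix_(idx, idx)]
    hr10, hr01, hr11 = np.exp(beta)
    reri = hr11 - hr10 - hr01 + 1.0
    grad = np.array([-hr10, -hr01, hr11])
    se = float(np.sqrt(grad @ V @ grad))
    z = 1.959963984540054
    return {
        "hr_product": float(s.loc["GxE", "hr"]),
        "p_product": float(s.loc["GxE", "p"]),
        "hr_joint": {"10": hr10, "01": hr01, "11": hr11},
        "reri": float(reri),
        "reri_ci": (float(reri - z * se), float(reri + z * se)),
        "reri_se": se,
    }


def schoenfeld_check(result: CoxResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportional-hazards diagnostic on scaled Schoenfeld residuals.

    For each covariate, the Pearson correlation rho between its scaled
    Schoenfeld residuals and the rank of the event times, with its p-value
    — a nonzero rho indicates a time-varying effect.  Returns (summary,
    residuals); the residual frame (per event time) is suitable for a
    residual-vs-time plot.
    """
    model = result.model
    if not isinstance(model, CoxPHFitter):
        raise ConfigurationError("schoenfeld_check needs an Efron/lifelines fit")
    resid = model.compute_residuals(result.data, "scaled_schoenfeld")
    event_times = result.data.loc[resid.index, "time"].to_numpy()
    order = np.argsort(event_times, kind="stable")
    ranks = np.empty(len(event_times))
    ranks[order] = np.arange(1, len(event_times) + 1)
    rows = []
    for col in resid.columns:
        r = resid[col].to_numpy()
        if len(r) < 3 or np.allclose(r, r[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.pearsonr(r, ranks)
        rows.append({"term": col, "rho": rho, "p": p})
    out = resid.copy()
    out.insert(0, "event_time", event_times)
    out.insert(1, "time_rank", ranks)
    return pd.DataFrame(rows), out.sort_values("event_time").reset_index(drop=True)
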