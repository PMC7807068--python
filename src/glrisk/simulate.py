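"""Synthetic postmenopausal-cohort generator with plantable survival effects.

The generator emulates the statistical structure the downstream analysis
assumes: SNP genotypes in Hardy-Weinberg equilibrium, lifestyle covariates
with realistic marginal distributions for a postmenopausal study population
(age ~ 66 y, ~5% cumulative breast-cancer incidence over a mean 16-year
follow-up, ~10% of women drinking >= 18 g alcohol/day), and a
proportional-hazards time-to-event outcome with user-planted main and
interaction effects.

Event times are exponential given the linear predictor (constant baseline
hazard, chosen for closed-form calibration of the marginal event fraction)
with administrative censoring at a Uniform(12, 20)-year horizon, giving a
mean 16-year follow-up among censored subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import Cohort, ConfigurationError, write_tables


@dataclass(frozen=True)
class CovariateSpec:
    """Distribution descriptor for one simulated covariate.

    Families
    --------
    ``normal``       params: mean, sd, optional low/high truncation bounds
    ``gamma``        params: shape, scale
    ``zigamma``      zero-inflated gamma; params: p_zero, shape, scale
    ``bernoulli``    params: p
    ``categorical``  params: levels (list), probs (list)
    ``constant``     params: value
    """

    family: str
    params: dict
    units: str = ""

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            x = rng.normal(p["mean"], p["sd"], n)
            low = p.get("low", -np.inf)
            high = p.get("high", np.inf)
            if np.isfinite(low) or np.isfinite(high):
                # resample out-of-range draws (truncation by rejection)
                bad = (x < low) | (x > high)
                while bad.any():
                    x[bad] = rng.normal(p["mean"], p["sd"], bad.sum())
                    bad = (x < low) | (x > high)
            return x
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], n)
        if self.family == "zigamma":
            x = rng.gamma(p["shape"], p["scale"], n)
            x[rng.random(n) < p["p_zero"]] = 0.0
            return x
        if self.family == "bernoulli":
            return (rng.random(n) < p["p"]).astype(float)
        if self.family == "categorical":
            return rng.choice(np.asarray(p["levels"]), size=n, p=p["probs"])
        if self.family == "constant":
            return np.full(n, float(p["value"]))
        raise ConfigurationError(f"unknown distribution family {self.family!r}")


@dataclass
class SimSpec:
    """Full description of a synthetic cohort.

    ``log_hr_map`` maps design-column names (SNP ids or covariate names) to
    log hazard ratios; genotype terms enter as additive 0/1/2 dosage unless
    the SNP appears in ``risk_indicators``, in which case a 0/1 carrier
    indicator of the listed genotype values is used.  ``interaction_terms``
    are (varA, varB, log-HR) triples on the same coding.
    """

    n: int
    mafs: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    covariate_specs: dict[str, CovariateSpec] = field(default_factory=dict)
    log_hr_map: dict[str, float] = field(default_factory=dict)
    interaction_terms: list[tuple[str, str, float]] = field(default_factory=list)
    risk_indicators: dict[str, tuple[float, ...]] = field(default_factory=dict)
    baseline_hazard: float = 0.0033
    followup: tuple[float, float] = (12.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.n < 2:
            raise ConfigurationError("need at least 2 subjects")
        if self.mafs.size and (np.any(self.mafs <= 0) or np.any(self.mafs > 0.5)):
            raise ConfigurationError("minor-allele frequencies must lie in (0, 0.5]")
        if self.baseline_hazard < 0:
            raise ConfigurationError("baseline hazard must be >= 0")
        if not self.snp_ids:
            self.snp_ids = [f"rs{i + 1:04d}" for i in range(self.mafs.size)]
        if len(self.snp_ids) != self.mafs.size:
            raise ConfigurationError("snp_ids and mafs lengths differ")


# ----------------------------------------------------------------------
# Component samplers
# ----------------------------------------------------------------------

def simulate_genotypes(
    n: int, mafs: Sequence[float], seed: int | np.random.Generator
) -> np.ndarray:
    """i.i.d. Hardy-Weinberg genotypes: dosage ~ Binomial(2, maf) per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ConfigurationError("minor-allele frequencies must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    return rng.binomial(2, mafs, size=(n, mafs.size)).astype(np.int8)


def simulate_lifestyles(
    n: int,
    covariate_specs: dict[str, CovariateSpec],
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    return pd.DataFrame(
        {name: spec.sample(n, rng) for name, spec in covariate_specs.items()}
    )


def _coded_column(values: np.ndarray, name: str, spec: SimSpec) -> np.ndarray:
    if name in spec.risk_indicators:
        return np.isin(values, spec.risk_indicators[name]).astype(float)
    return np.asarray(values, dtype=float)


def linear_predictor(
    design: pd.DataFrame, spec: SimSpec
) -> np.ndarray:
    """Planted log-hazard linear predictor over a genotype+covariate frame."""
    lp = np.zeros(len(design))
    for name, beta in spec.log_hr_map.items():
        if name not in design.columns:
            raise ConfigurationError(f"log_hr_map term {name!r} not in design")
        lp += beta * _coded_column(design[name].to_numpy(), name, spec)
    for a, b, beta in spec.interaction_terms:
        for v in (a, b):
            if v not in design.columns:
                raise ConfigurationError(f"interaction term {v!r} not in design")
        lp += (
            beta
            * _coded_column(design[a].to_numpy(), a, spec)
            * _coded_column(design[b].to_numpy(), b, spec)
        )
    if not np.all(np.isfinite(lp)):
        raise ConfigurationError("non-finite linear predictor")
    return lp


def simulate_survival(
    lp: np.ndarray,
    baseline_hazard: float,
    followup: tuple[float, float],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times under PH with administrative censoring.

    ``T ~ Exp(rate = baseline_hazard * exp(lp))``, censoring horizon
    ``C ~ Uniform(followup)``; returns (observed time, event indicator).
    """
    if not np.all(np.isfinite(lp)):
        raise ConfigurationError("non-finite linear predictor")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n = len(lp)
    cens = rng.uniform(followup[0], followup[1], n)
    rate = baseline_hazard * np.exp(lp)
    if baseline_hazard == 0:
        return cens, np.zeros(n, dtype=np.int8)
    t = rng.exponential(1.0, n) / rate
    event = (t <= cens).astype(np.int8)
    return np.minimum(t, cens), event


def expected_event_fraction(
    baseline_hazard: float, lp: np.ndarray, followup: tuple[float, float]
) -> float:
    """Closed-form P(event) under the exponential + uniform-censoring model.

    For rate lambda and C ~ U(a, b):
    P(T <= C) = 1 - (exp(-lambda a) - exp(-lambda b)) / (lambda (b - a)),
    averaged over the empirical linear-predictor distribution.
    """
    a, b = followup
    lam = baseline_hazard * np.exp(np.asarray(lp, dtype=float))
    lam = np.maximum(lam, 1e-300)
    frac = 1.0 - (np.exp(-lam * a) - np.exp(-lam * b)) / (lam * (b - a))
    return float(frac.mean())


def calibrate_baseline_hazard(
    target_event_fraction: float,
    lp: np.ndarray,
    followup: tuple[float, float] = (12.0, 20.0),
) -> float:
    """Solve for the constant baseline hazard hitting a marginal event rate."""
    f = lambda h: expected_event_fraction(h, lp, followup) - target_event_fraction
    return float(brentq(f, 1e-10, 10.0, xtol=1e-12))


# ----------------------------------------------------------------------
# Study-scale defaults
# ----------------------------------------------------------------------

def default_covariate_specs() -> dict[str, CovariateSpec]:
    """Marginal covariate distributions for a postmenopausal US cohort.

    Parameterized from the first moments typical of such cohorts: age
    66 (SD 6.65) truncated to the 50-79 enrollment window (the location
    parameters of truncated normals are pre-solved so the *truncated*
    means hit their targets); BMI ~ 27.8
    kg/m^2; mean dietary alcohol ~ 6 g/day with ~10% of women at or above
    18 g/day (zero-inflated gamma); exercise ~ 11 MET-h/week; hormone-use
    durations as zero-inflated gammas matching never-use fractions of
    ~82% (E+P) and ~70% (E-only).  Covariates are drawn independently;
    see the methods note for what that does and does not emulate.
    """
    return {
        "age": CovariateSpec("normal", {"mean": 66.309, "sd": 6.65, "low": 50, "high": 79}, "years"),
        "alcohol": CovariateSpec("zigamma", {"p_zero": 0.30, "shape": 0.62, "scale": 14.1}, "g/day"),
        "bmi": CovariateSpec("normal", {"mean": 27.661, "sd": 5.4, "low": 15, "high": 60}, "kg/m^2"),
        "waist": CovariateSpec("normal", {"mean": 86.8, "sd": 12.8, "low": 50, "high": 160}, "cm"),
        "hip": CovariateSpec("normal", {"mean": 106.5, "sd": 11.1, "low": 60, "high": 180}, "cm"),
        "whr": CovariateSpec("normal", {"mean": 0.814, "sd": 0.073, "low": 0.5, "high": 1.2}, "ratio"),
        "met": CovariateSpec("zigamma", {"p_zero": 0.12, "shape": 0.9, "scale": 13.9}, "MET-h/week"),
        "sfa_pct": CovariateSpec("normal", {"mean": 11.4, "sd": 2.8, "low": 2, "high": 33}, "% calories"),
        "protein_pct": CovariateSpec("normal", {"mean": 16.7, "sd": 3.05, "low": 5, "high": 35}, "% calories"),
        "cigarettes_per_day": CovariateSpec("zigamma", {"p_zero": 0.52, "shape": 1.5, "scale": 12.0}, "cigarettes"),
        "depressive_symptom": CovariateSpec("zigamma", {"p_zero": 0.75, "shape": 0.5, "scale": 0.22}, "scale"),
        "income_ge_35k": CovariateSpec("bernoulli", {"p": 0.531}),
        "education_gt_hs": CovariateSpec("bernoulli", {"p": 0.64}),
        "famhist_breast_cancer": CovariateSpec("bernoulli", {"p": 0.19}),
        "age_menopause": CovariateSpec("normal", {"mean": 48.175, "sd": 6.2, "low": 30, "high": 62}, "years"),
        "age_menarche": CovariateSpec("normal", {"mean": 13.0, "sd": 1.44, "low": 9, "high": 18}, "years"),
        "oc_years": CovariateSpec("zigamma", {"p_zero": 0.55, "shape": 2.6, "scale": 2.2}, "years"),
        "ep_years": CovariateSpec("zigamma", {"p_zero": 0.82, "shape": 1.1, "scale": 4.6}, "years"),
        "e_only_years": CovariateSpec("zigamma", {"p_zero": 0.70, "shape": 1.1, "scale": 5.2}, "years"),
        "hysterectomy": CovariateSpec("bernoulli", {"p": 0.36}),
    }


def default_simspec(
    n: int = 10179,
    n_snps: int = 156,
    seed: int = 0,
    with_effects: bool = True,
    target_event_fraction: float = 537 / 10179,
) -> SimSpec:
    """Study-scale simulation defaults: ~10k women, 156 SNPs, ~5.3% events.

    With ``with_effects`` the generator plants modest proportional-hazards
    effects on five risk-genotype indicators and four risk lifestyles (the
    pattern the profiling stage is designed to detect), plus one
    gene-lifestyle interaction.  MAFs are drawn once from Uniform(0.05,
    0.5) under ``seed``.
    """
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(0.05, 0.5, n_snps)
    snp_ids = [f"rs{i + 1:04d}" for i in range(n_snps)]
    spec = SimSpec(
        n=n,
        mafs=mafs,
        snp_ids=snp_ids,
        covariate_specs=default_covariate_specs(),
        seed=seed,
    )
    if with_effects and n_snps >= 5:
        # Five planted risk SNPs: carrier (dominant) or homozygote
        # (recessive) indicators, mirroring risk-genotype dichotomies.
        spec.risk_indicators = {
            snp_ids[0]: (1.0, 2.0),
            snp_ids[1]: (2.0,),
            snp_ids[2]: (2.0,),
            snp_ids[3]: (2.0,),
            snp_ids[4]: (1.0, 2.0),
        }
        spec.log_hr_map = {
            snp_ids[0]: np.log(1.5),
            snp_ids[1]: np.log(1.6),
            snp_ids[2]: np.log(1.5),
            snp_ids[3]: np.log(1.7),
            snp_ids[4]: np.log(1.4),
            "alcohol_ge_18": np.log(1.4),
            "ep_years_ge_10": np.log(1.4),
            "oc_years_lt_5": np.log(1.2),
            "bmi": 0.035,
        }
        spec.interaction_terms = [(snp_ids[3], "alcohol_ge_18", np.log(1.3))]
    # Baseline hazard calibrated below in simulate_cohort against the
    # realized linear predictor; store the null-model solution as default.
    spec.baseline_hazard = calibrate_baseline_hazard(
        target_event_fraction, np.zeros(1), spec.followup
    )
    return spec


_DERIVED_BINARIES: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "alcohol_ge_18": lambda c: (c["alcohol"] >= 18).astype(float).to_numpy(),
    "ep_years_ge_10": lambda c: (c["ep_years"] >= 10).astype(float).to_numpy(),
    "oc_years_lt_5": lambda c: (c["oc_years"] < 5).astype(float).to_numpy(),
    "bmi_ge_30": lambda c: (c["bmi"] >= 30).astype(float).to_numpy(),
}


def simulate_cohort(
    spec: SimSpec,
    calibrate_to: float | None = None,
) -> Cohort:
    """Draw a full cohort (genotypes, covariates, survival outcome).

    When ``calibrate_to`` is given, the baseline hazard is re-solved so the
    *marginal* expected event fraction, averaged over the realized linear
    predictor, equals the target.  Identical specs (same seed) produce
    byte-identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    geno = simulate_genotypes(spec.n, spec.mafs, rng)
    geno_df = pd.DataFrame(geno, columns=spec.snp_ids)
    cov = simulate_lifestyles(spec.n, spec.covariate_specs, rng)

    design = pd.concat([geno_df.astype(float), cov], axis=1)
    for name, fn in _DERIVED_BINARIES.items():
        needed = name in spec.log_hr_map or any(
            name in (a, b) for a, b, _ in spec.interaction_terms
        )
        if needed and name not in design.columns:
            design[name] = fn(cov)
    lp = linear_predictor(design, spec)
    lp = lp - lp.mean()  # planted effects shift risk; center so the
    # baseline hazard keeps its marginal-rate interpretation
    h0 = spec.baseline_hazard
    if calibrate_to is not None:
        h0 = calibrate_baseline_hazard(calibrate_to, lp, spec.followup)
    time, event = simulate_survival(lp, h0, spec.followup, rng)

    ids = np.array([f"S{i + 1:06d}" for i in range(spec.n)])
    snp_meta = pd.DataFrame(
        {"snp": spec.snp_ids, "gene": "", "maf": spec.mafs}
    )
    return Cohort(
        subject_ids=ids,
        genotypes=geno_df,
        covariates=cov,
        time_years=time,
        event=event,
        snp_meta=snp_meta,
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the three-table cohort_data dialect."""
    return write_tables(cohort, out_dir)
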