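"""Cohort data model, file I/O, genotype QC and obesity-stratum construction.

A :class:`Cohort` bundles the three aligned tables the rest of the package
works on: a subjects x SNPs genotype matrix of minor-allele counts (0/1/2,
``NaN`` for missing), a covariate table of continuous and categorical
lifestyle variables, and a right-censored survival outcome (follow-up time
in years plus a binary event indicator).

Genotype quality control follows the usual GWAS conventions: SNPs are
removed when their missing-call rate reaches 2% or when an exact test of
Hardy-Weinberg equilibrium rejects at p < 1e-4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln


class CohortError(Exception):
    """Base class for cohort construction and configuration problems."""


class AlignmentError(CohortError):
    """Subject identifiers do not line up across the input tables."""


class GenotypeFormatError(CohortError):
    """A genotype entry is not in {0, 1, 2, missing}."""


class ValidationError(CohortError):
    """A cohort invariant is violated (e.g. nonpositive follow-up time)."""


class ConfigurationError(CohortError):
    """A requested variable, rule or parameter does not exist / is invalid."""


_MISSING_CODES = {"NA", "NaN", "nan", ".", "-9", ""}


@dataclass(frozen=True)
class StratumSpec:
    """A binary stratification rule on one continuous covariate.

    ``low_inclusive`` pins the boundary convention: the low stratum is
    ``value <= cutoff`` when True and ``value < cutoff`` when False.  The
    conventions differ between obesity measures (BMI is dichotomized as
    <30 vs >=30 while WHR is <=0.85 vs >0.85), so they are stored per
    stratum rather than hard-coded.
    """

    variable: str
    cutoff: float
    low_inclusive: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ConfigurationError(f"non-finite cutoff for {self.variable!r}")

    def low_mask(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return v <= self.cutoff if self.low_inclusive else v < self.cutoff


#: Obesity / obesity-related lifestyle strata with their conventional cutoffs:
#: overall obesity (BMI, 30 kg/m^2), abdominal obesity (waist, 88 cm),
#: visceral obesity (waist-to-hip ratio, 0.85), exercise dose (10 MET-h/week)
#: and dietary fat (9% of calories from saturated fatty acids).
DEFAULT_STRATA: dict[str, StratumSpec] = {
    "bmi": StratumSpec("bmi", 30.0, low_inclusive=False),
    "waist": StratumSpec("waist", 88.0, low_inclusive=True),
    "whr": StratumSpec("whr", 0.85, low_inclusive=True),
    "met": StratumSpec("met", 10.0, low_inclusive=False),
    "sfa_pct": StratumSpec("sfa_pct", 9.0, low_inclusive=False),
}


@dataclass
class Cohort:
    """Aligned genotype, covariate and survival-outcome tables.

    Attributes
    ----------
    subject_ids : ndarray of str
        Unique subject identifiers, one per row of every table.
    genotypes : DataFrame
        n x p matrix of minor-allele counts in {0, 1, 2}; missing = NaN.
    covariates : DataFrame
        Named lifestyle/clinical columns (continuous or categorical).
    time_years : ndarray of float
        Strictly positive follow-up time in years.
    event : ndarray of int
        Binary event indicator (1 = incident case).
    snp_meta : DataFrame
        Per-SNP metadata: ``snp`` id, ``gene`` label, ``maf``.
    """

    subject_ids: np.ndarray
    genotypes: pd.DataFrame
    covariates: pd.DataFrame
    time_years: np.ndarray
    event: np.ndarray
    snp_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.time_years = np.asarray(self.time_years, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.subject_ids)
        if len(np.unique(self.subject_ids)) != n:
            raise ValidationError("subject ids are not unique")
        for name, comp in (
            ("genotypes", self.genotypes),
            ("covariates", self.covariates),
            ("time_years", self.time_years),
            ("event", self.event),
        ):
            if len(comp) != n:
                raise AlignmentError(
                    f"{name} has {len(comp)} rows, expected {n}"
                )
        if np.any(~np.isfinite(self.time_years)) or np.any(self.time_years <= 0):
            raise ValidationError("follow-up times must be finite and > 0")
        ev = np.unique(self.event)
        if not np.isin(ev, [0, 1]).all():
            raise ValidationError(f"event indicator must be binary, got {ev}")
        self.event = self.event.astype(np.int8)
        g = self.genotypes.to_numpy(dtype=float)
        bad = np.isfinite(g) & ~np.isin(g, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeFormatError(
                f"genotype value {g[i, j]!r} for subject "
                f"{self.subject_ids[i]!r}, SNP {self.genotypes.columns[j]!r}"
            )
        if self.snp_meta is None:
            self.snp_meta = _default_snp_meta(self.genotypes)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def snps(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates.columns)

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset every component with a boolean mask or index array."""
        mask = np.asarray(mask)
        return Cohort(
            subject_ids=self.subject_ids[mask],
            genotypes=self.genotypes.iloc[mask].reset_index(drop=True),
            covariates=self.covariates.iloc[mask].reset_index(drop=True),
            time_years=self.time_years[mask],
            event=self.event[mask],
            snp_meta=self.snp_meta,
        )

    def keep_snps(self, snps: Iterable[str]) -> "Cohort":
        snps = list(snps)
        return Cohort(
            subject_ids=self.subject_ids,
            genotypes=self.genotypes[snps],
            covariates=self.covariates,
            time_years=self.time_years,
            event=self.event,
            snp_meta=self.snp_meta[self.snp_meta["snp"].isin(snps)].reset_index(
                drop=True
            ),
        )

    def imputed_genotypes(self) -> pd.DataFrame:
        """Genotypes with per-SNP mode imputation of missing calls.

        Mode imputation preserves the marginal genotype distribution at the
        missingness rates tolerated by QC (< 2%) and keeps the matrix in
        {0,1,2} so downstream cell-based methods stay well defined.
        """
        g = self.genotypes.copy()
        for col in g.columns:
            v = g[col]
            if v.isna().any():
                obs = v.dropna()
                fill = obs.mode().iloc[0] if len(obs) else 0.0
                g[col] = v.fillna(fill)
        return g


def _default_snp_meta(genotypes: pd.DataFrame) -> pd.DataFrame:
    g = genotypes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(g, axis=0) / 2.0 if g.size else np.array([])
    return pd.DataFrame(
        {"snp": list(genotypes.columns), "gene": "", "maf": maf}
    )


# ----------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------

def read_cohort(
    genotype_path: str | Path,
    covariate_path: str | Path,
    outcome_path: str | Path,
    schema: dict | str | Path | None = None,
) -> Cohort:
    """Read the three tab-delimited cohort tables and join them on subject id.

    Each file carries a header row and a leading ``subject_id`` column.  The
    outcome table must provide ``time_years`` and ``event`` columns.  Missing
    genotypes may be coded as NA/NaN/./-9 and are normalized to NaN.

    ``schema`` is an optional JSON sidecar (path or already-parsed dict)
    declaring covariate types/units and stratum specs; when given, declared
    columns are required to be present.
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str)
    cov = pd.read_csv(covariate_path, sep="\t")
    out = pd.read_csv(outcome_path, sep="\t")
    for name, df in (("genotype", geno), ("covariate", cov), ("outcome", out)):
        if df.columns[0] != "subject_id":
            raise AlignmentError(
                f"{name} table must start with a subject_id column"
            )

    if isinstance(schema, (str, Path)):
        schema = json.loads(Path(schema).read_text())
    if schema:
        declared = set(schema.get("covariates", {}))
        missing = declared - set(cov.columns)
        if missing:
            raise ConfigurationError(
                f"covariate columns declared in schema but absent: {sorted(missing)}"
            )

    ids = geno["subject_id"].to_numpy()
    for name, df in (("covariate", cov), ("outcome", out)):
        other = df["subject_id"].astype(str).to_numpy()
        if set(other) != set(ids.astype(str)):
            raise AlignmentError(
                f"{name} table subject ids do not match the genotype table"
            )
    cov = cov.set_index(cov["subject_id"].astype(str)).loc[ids.astype(str)]
    out = out.set_index(out["subject_id"].astype(str)).loc[ids.astype(str)]

    gmat = geno.drop(columns="subject_id").replace(sorted(_MISSING_CODES), np.nan)
    gmat = gmat.apply(pd.to_numeric, errors="raise")

    if "time_years" not in out.columns or "event" not in out.columns:
        raise ConfigurationError("outcome table needs time_years and event columns")

    return Cohort(
        subject_ids=ids,
        genotypes=gmat.reset_index(drop=True),
        covariates=cov.drop(columns="subject_id").reset_index(drop=True),
        time_years=out["time_years"].to_numpy(dtype=float),
        event=out["event"].to_numpy(),
    )


def write_tables(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort back to the three-table tab-delimited dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "covariates": out_dir / "covariates.tsv",
        "outcome": out_dir / "outcome.tsv",
    }
    g = cohort.genotypes.copy()
    g.insert(0, "subject_id", cohort.subject_ids)
    g.to_csv(paths["genotypes"], sep="\t", index=False, na_rep="NA")
    c = cohort.covariates.copy()
    c.insert(0, "subject_id", cohort.subject_ids)
    c.to_csv(paths["covariates"], sep="\t", index=False)
    o = pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "time_years": cohort.time_years,
            "event": cohort.event,
        }
    )
    o.to_csv(paths["outcome"], sep="\t", index=False)
    return paths


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and computes the probability,
    under HWE, of every heterozygote count compatible with them; the p-value
    is the total probability of configurations no more likely than the
    observed one (the standard exact SNP-HWE construction).

    Parameters are the three genotype counts (major homozygote,
    heterozygote, minor homozygote); their labels do not matter because the
    test is symmetric in the two alleles.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero; HWE test undefined")
    n_het = counts[1]
    n_rare = 2 * min(counts[0], counts[2]) + n_het  # minor-allele count
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: a single configuration exists

    # All heterozygote counts share the parity of the minor-allele count.
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(het | allele counts) up to a shared constant:
    #   P(h) ∝ 2^h / (h! * ((n_rare-h)/2)! * ((2n-n_rare-h)/2)!)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


# ----------------------------------------------------------------------
# QC filter
# ----------------------------------------------------------------------

def qc_filter(
    cohort: Cohort,
    max_missing_rate: float = 0.02,
    min_hwe_p: float = 1e-4,
) -> tuple[Cohort, pd.DataFrame]:
    """Remove SNPs failing missing-call-rate or Hardy-Weinberg filters.

    A SNP is kept when its missing-call rate is strictly below
    ``max_missing_rate`` and its HWE exact p-value is at least
    ``min_hwe_p`` (computed on the non-missing calls).  Returns the
    filtered cohort and a report listing every removed SNP with the reason
    and the offending value.
    """
    for name, thr in (("max_missing_rate", max_missing_rate), ("min_hwe_p", min_hwe_p)):
        if not 0 < thr < 1:
            raise ConfigurationError(f"{name} must lie in (0, 1), got {thr}")
    g = cohort.genotypes.to_numpy(dtype=float)
    records = []
    keep = []
    for j, snp in enumerate(cohort.snps):
        col = g[:, j]
        miss = np.isnan(col).mean()
        if miss >= max_missing_rate:
            records.append((snp, "missing_rate", miss))
            continue
        obs = col[~np.isnan(col)]
        counts = [(obs == k).sum() for k in (0, 1, 2)]
        p = hwe_exact_test(*counts) if obs.size else 1.0
        if p < min_hwe_p:
            records.append((snp, "hwe", p))
            continue
        keep.append(snp)
    report = pd.DataFrame(records, columns=["snp", "reason", "value"])
    if not keep:
        import warnings

        warnings.warn("qc_filter removed every SNP", stacklevel=2)
    return cohort.keep_snps(keep), report


# ----------------------------------------------------------------------
# Stratification
# ----------------------------------------------------------------------

def stratify(
    cohort: Cohort,
    spec: StratumSpec,
    missing: str = "error",
) -> tuple[Cohort, Cohort]:
    """Partition a cohort into (low, high) strata on one covariate.

    The boundary convention comes from ``spec.low_inclusive``.  Missing
    values in the stratification variable either raise (``missing='error'``,
    default) or drop the affected subjects (``missing='drop'``).
    """
    if spec.variable not in cohort.covariates.columns:
        raise ConfigurationError(
            f"stratification variable {spec.variable!r} not in covariates"
        )
    v = cohort.covariates[spec.variable].to_numpy(dtype=float)
    isna = ~np.isfinite(v)
    if isna.any():
        if missing == "error":
            raise ValidationError(
                f"{isna.sum()} missing values in {spec.variable!r}; "
                "pass missing='drop' to exclude them"
            )
        cohort = cohort.subset(~isna)
        v = v[~isna]
    low = spec.low_mask(v)
    return cohort.subset(low), cohort.subset(~low)
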