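"""Generalized multifactor dimensionality reduction (GMDR).

GMDR collapses a multilocus genotype combination to a single high/low-risk
dimension.  Each subject carries a *score residual* from a null phenotype
model with adjustment covariates (logistic by default, martingale residuals
from a null proportional-hazards model as an option).  Subjects are binned
into multilocus genotype cells; a cell is high-risk when its summed score
is positive.  Predictive value is measured by 10-fold cross-validated
testing balanced accuracy (TBA), model stability by cross-validation
consistency (CVC: in how many folds the same combination wins), and
significance by a permutation test of the TBA.

The best model across interaction orders is the one with the highest TBA
among models with full CVC and a significant permutation p; when no model
qualifies, full CVC takes precedence and the choice is flagged
non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ConfigurationError


class ScoreError(Exception):
    """Null phenotype model failed (separation / non-convergence)."""


# ----------------------------------------------------------------------
# Scores
# ----------------------------------------------------------------------

def compute_scores(
    event: np.ndarray,
    covariates: pd.DataFrame | None = None,
    model: str = "logistic",
    time: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate-adjusted score residuals for GMDR.

    ``logistic``: response residuals ``y - p_hat`` from a null logistic
    model of the binary event on the adjustment covariates (intercept-only
    when none are given).  ``martingale``: martingale residuals from a null
    Cox model, which carry the time-to-event information.
    """
    y = np.asarray(event, dtype=float)
    if not np.isin(np.unique(y), [0.0, 1.0]).all():
        raise ConfigurationError("event must be binary for GMDR scoring")
    if model == "logistic":
        if covariates is not None and len(covariates.columns):
            X = sm.add_constant(np.asarray(covariates, dtype=float))
        else:
            X = np.ones((len(y), 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        except Exception as exc:  # pragma: no cover - statsmodels internals
            raise ScoreError(f"null logistic model failed: {exc}") from exc
        if not np.all(np.isfinite(fit.params)):
            raise ScoreError("null logistic model diverged (separation?)")
        return np.asarray(y - fit.fittedvalues)
    if model == "martingale":
        if time is None:
            raise ConfigurationError("martingale scores need event times")
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"time": np.asarray(time, dtype=float), "event": y})
        if covariates is not None and len(covariates.columns):
            df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            mart = cph.compute_residuals(df, "martingale")["martingale"]
            return mart.sort_index().to_numpy()
        # null model without covariates: y - Nelson-Aalen at observed time
        from .forest import nelson_aalen_on_grid

        t = df["time"].to_numpy()
        grid = np.unique(t)
        chf = nelson_aalen_on_grid(t, y, grid)
        return y - chf[np.searchsorted(grid, t)]
    raise ConfigurationError(f"unknown score model {model!r}")


# ----------------------------------------------------------------------
# Cells
# ----------------------------------------------------------------------

def _cell_index(genotypes: np.ndarray) -> tuple[np.ndarray, int]:
    """Mixed-radix (base-3) index of each subject's multilocus cell."""
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[:, None]
    if not np.isin(np.unique(g), [0, 1, 2]).all():
        raise ConfigurationError("genotypes must be 0/1/2 (impute missing first)")
    k = g.shape[1]
    radix = 3 ** np.arange(k)
    return (g.astype(np.int64) @ radix), 3**k


def classify_cells(
    scores: np.ndarray,
    genotypes: np.ndarray,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Label every multilocus genotype cell high- or low-risk.

    A cell is high-risk when its member scores sum above ``threshold``;
    ties go to low-risk (conservative, deterministic).  Empty cells are
    marked unclassifiable (label ``-1``) and carry zero weight in accuracy
    computations.
    """
    scores = np.asarray(scores, dtype=float)
    cell, n_cells = _cell_index(genotypes)
    count = np.bincount(cell, minlength=n_cells)
    total = np.bincount(cell, weights=scores, minlength=n_cells)
    label = np.where(count == 0, -1, (total > threshold).astype(int))
    return pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "count": count,
            "score_sum": total,
            "label": label,
        }
    )


# ----------------------------------------------------------------------
# Cross-validation
# ----------------------------------------------------------------------

def _fold_assignment(
    strat: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels stratified on a binary indicator, fixed by the rng."""
    n = len(strat)
    fold = np.empty(n, dtype=np.int32)
    for level in np.unique(strat):
        idx = np.flatnonzero(strat == level)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = np.arange(len(idx)) % folds
    return fold


def _ba_from_cells(
    cell: np.ndarray,
    pos: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
) -> float:
    """Balanced accuracy of cell-label predictions on masked subjects.

    Truth is the subject's score sign (positive score = case-like);
    prediction is the (training-derived) cell label, with unclassifiable
    cells predicted low-risk.
    """
    pred = labels[cell[mask]] == 1
    truth = pos[mask]
    P = truth.sum()
    N = (~truth).sum()
    if P == 0 or N == 0:
        return np.nan
    sens = (pred & truth).sum() / P
    spec = (~pred & ~truth).sum() / N
    return 0.5 * (sens + spec)


def _train_labels(
    cell: np.ndarray, scores: np.ndarray, train: np.ndarray, n_cells: int,
    threshold: float,
) -> np.ndarray:
    total = np.bincount(cell[train], weights=scores[train], minlength=n_cells)
    count = np.bincount(cell[train], minlength=n_cells)
    labels = (total > threshold).astype(np.int8)
    labels[count == 0] = 0  # empty-in-training cells predict low risk
    return labels


def cv_evaluate(
    scores: np.ndarray,
    genotypes: np.ndarray,
    folds: int = 10,
    seed: int | np.random.Generator = 0,
    strat: np.ndarray | None = None,
    threshold: float = 0.0,
    fold_labels: np.ndarray | None = None,
) -> tuple[float, float]:
    """(training balanced accuracy, testing balanced accuracy) by k-fold CV.

    Per fold, cells are classified on the training subjects and evaluated
    on the held-out subjects; TBA is the mean test balanced accuracy over
    folds.  Folds with only one truth class are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if folds < 2 or n < folds:
        raise ConfigurationError("need folds >= 2 and n >= folds")
    cell, n_cells = _cell_index(genotypes)
    pos = scores > 0
    if fold_labels is None:
        rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
        fold_labels = _fold_assignment(
            strat if strat is not None else pos, folds, rng
        )
    train_ba, test_ba = [], []
    for f in range(folds):
        test = fold_labels == f
        train = ~test
        labels = _train_labels(cell, scores, train, n_cells, threshold)
        tr = _ba_from_cells(cell, pos, labels, train)
        te = _ba_from_cells(cell, pos, labels, test)
        if np.isnan(te):
            warnings.warn(f"fold {f} has a single truth class; skipped", stacklevel=2)
            continue
        train_ba.append(tr)
        test_ba.append(te)
    if not test_ba:
        raise ConfigurationError("no evaluable folds")
    return float(np.nanmean(train_ba)), float(np.mean(test_ba))


# ----------------------------------------------------------------------
# Model search
# ----------------------------------------------------------------------

@dataclass
class GMDRResult:
    """Best factor combination at one interaction order."""

    combo: tuple[str, ...]
    order: int
    tba: float
    train_ba: float
    cvc: int
    folds: int
    per_fold_best: list[tuple[str, ...]] = field(default_factory=list)
    p_value: float | None = None
    significant: bool | None = None

    def as_row(self) -> dict:
        return {
            "order": self.order,
            "model": ", ".join(self.combo),
            "tba": self.tba,
            "p_value": self.p_value,
            "cvc": f"{self.cvc}/{self.folds}",
        }


def model_search(
    scores: np.ndarray,
    genotypes: pd.DataFrame,
    snp_pool: Sequence[str] | None = None,
    max_order: int = 5,
    folds: int = 10,
    seed: int = 0,
    strat: np.ndarray | None = None,
    pool_cap: int = 25,
) -> list[GMDRResult]:
    """Exhaustive combination search, one best model per interaction order.

    Per fold the top training-BA combination is recorded; the reported
    combination is the plurality winner across folds (CVC = its number of
    winning folds) and its TBA comes from the same cross-validation split.
    """
    pool = list(snp_pool) if snp_pool is not None else list(genotypes.columns)
    if len(pool) > pool_cap:
        raise ConfigurationError(
            f"SNP pool of {len(pool)} exceeds the combinatorial cap "
            f"({pool_cap}); raise pool_cap explicitly to proceed"
        )
    if len(pool) < max_order:
        raise ConfigurationError("pool smaller than max_order")
    scores = np.asarray(scores, dtype=float)
    G = genotypes[pool].to_numpy()
    rng = np.random.default_rng(seed)
    pos = scores > 0
    fold_labels = _fold_assignment(
        strat if strat is not None else pos, folds, rng
    )
    results = []
    for order in range(1, max_order + 1):
        combos = list(combinations(range(len(pool)), order))
        # per-fold best combination by training balanced accuracy
        best_per_fold: list[tuple[int, ...]] = []
        train_ba_cache: dict[tuple[int, ...], list[float]] = {}
        cells = {}
        for c in combos:
            cells[c] = _cell_index(G[:, c])
        for f in range(folds):
            train = fold_labels != f
            best_ba, best_c = -np.inf, None
            for c in combos:
                cell, n_cells = cells[c]
                labels = _train_labels(cell, scores, train, n_cells, 0.0)
                ba = _ba_from_cells(cell, pos, labels, train)
                train_ba_cache.setdefault(c, []).append(ba)
                if ba > best_ba:  # ties: first in lexicographic order
                    best_ba, best_c = ba, c
            best_per_fold.append(best_c)
        # plurality winner; ties broken by mean training BA then lex order
        from collections import Counter

        tally = Counter(best_per_fold)
        top = max(tally.values())
        tied = [c for c, k in tally.items() if k == top]
        winner = sorted(
            tied, key=lambda c: (-np.nanmean(train_ba_cache[c]), c)
        )[0]
        cvc = int(top)
        cell, n_cells = cells[winner]
        train_ba, tba = cv_evaluate(
            scores, G[:, winner], folds=folds, fold_labels=fold_labels
        )
        results.append(
            GMDRResult(
                combo=tuple(pool[i] for i in winner),
                order=order,
                tba=tba,
                train_ba=train_ba,
                cvc=cvc,
                folds=folds,
                per_fold_best=[tuple(pool[i] for i in c) for c in best_per_fold],
            )
        )
    return results


def permutation_test(
    scores: np.ndarray,
    genotypes: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    folds: int = 10,
    observed_tba: float | None = None,
) -> float:
    """One-sided permutation p for a combination's TBA.

    Scores are permuted against the genotype rows ``n_perm`` times and the
    TBA re-evaluated; p = (1 + #{perm TBA >= observed}) / (n_perm + 1), so
    p is never below 1/(n_perm + 1).
    """
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    if observed_tba is None:
        _, observed_tba = cv_evaluate(scores, genotypes, folds=folds, seed=rng)
    cell, n_cells = _cell_index(genotypes)
    pos = scores > 0
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(scores))
        s = scores[perm]
        fold_labels = _fold_assignment(s > 0, folds, rng)
        _, tba = cv_evaluate(
            s, genotypes, folds=folds, fold_labels=fold_labels
        )
        if tba >= observed_tba - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def select_best(
    results: Sequence[GMDRResult], alpha: float = 0.05
) -> GMDRResult:
    """Best model: highest TBA among full-CVC, permutation-significant models.

    Fallback when none qualifies: restrict to the models with the highest
    CVC, take the highest TBA among them, and flag the result
    non-significant.
    """
    if not results:
        raise ConfigurationError("no GMDR results to select from")
    qualified = [
        r
        for r in results
        if r.cvc == r.folds and r.p_value is not None and r.p_value < alpha
    ]
    if qualified:
        best = max(qualified, key=lambda r: r.tba)
        best.significant = True
        return best
    top_cvc = max(r.cvc for r in results)
    pool = [r for r in results if r.cvc == top_cvc]
    best = max(pool, key=lambda r: r.tba)
    best.significant = False
    return best


def results_table(results: Sequence[GMDRResult], best: GMDRResult | None = None) -> pd.DataFrame:
    """Tab-delimited-ready report (order, model, TBA, p, CVC, best flag)."""
    rows = [r.as_row() for r in results]
    df = pd.DataFrame(rows)
    df["best"] = [best is not None and r is best for r in results]
    return df
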