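"""From-scratch random survival forest with log-rank splitting.

Each tree is grown on a bootstrap sample (drawn with replacement, so about
63% of subjects are in-bag and 37% out-of-bag), splitting nodes to maximize
the standardized two-sample log-rank statistic over a random subset of
candidate variables and random candidate split points.  Terminal nodes hold
Nelson-Aalen cumulative-hazard estimators; the ensemble cumulative hazard is
the average over trees, and ensemble "mortality" (the sum of the ensemble
CHF over the event-time grid) serves as the risk score for Harrell's
concordance.

On top of the forest the module provides the variable-ranking machinery the
two-stage selection procedure needs:

* minimal depth (MD): per tree, the depth of the first node split on a
  variable (root = 0; unused variables contribute tree depth + 1), averaged
  over trees — small MD means the variable splits close to the root and is
  highly predictive;
* permutation VIMP: the drop in out-of-bag concordance when a variable's
  values are permuted among each tree's out-of-bag subjects;
* nested out-of-bag error curves: the OOB error (1 - concordance) of
  forests on the top-k ranked variables, with the null (k = 0) model's
  error fixed at 0.5, and the per-variable "drop error"
  d_k = e_{k-1} - e_k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ConfigurationError


class FitError(Exception):
    """Forest cannot be grown / evaluated on this input."""


@dataclass(frozen=True)
class ForestConfig:
    """Random-survival-forest hyperparameters.

    ``n_trees`` defaults to 5000 (the analysis-scale setting); tests and
    small runs pass far fewer.  ``mtry`` is the number of candidate
    variables per split (default ceil(sqrt(p))); ``nsplit`` the number of
    random candidate split points per variable; ``min_events`` the minimum
    number of events each daughter node must retain for a split to be
    admissible.
    """

    n_trees: int = 5000
    mtry: int | None = None
    min_events: int = 3
    max_depth: int | None = None
    nsplit: int = 10
    vimp_reps: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ConfigurationError("mtry must be >= 1")


class _Tree:
    """Array-based survival tree (internal)."""

    __slots__ = (
        "feature",
        "threshold",
        "left",
        "right",
        "depth",
        "leaf_id",
        "leaf_chf",
        "inbag",
        "oob",
        "first_split_depth",
        "max_depth",
    )

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.depth: list[int] = []
        self.leaf_id: list[int] = []
        self.leaf_chf: np.ndarray | None = None  # (n_leaves, n_grid)
        self.inbag: np.ndarray | None = None
        self.oob: np.ndarray | None = None
        self.first_split_depth: np.ndarray | None = None
        self.max_depth: int = 0

    def new_node(self, depth: int) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.depth.append(depth)
        self.leaf_id.append(-1)
        self.max_depth = max(self.max_depth, depth)
        return len(self.feature) - 1

    def finalize(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.int32)
        self.threshold = np.asarray(self.threshold, dtype=float)
        self.left = np.asarray(self.left, dtype=np.int32)
        self.right = np.asarray(self.right, dtype=np.int32)
        self.depth = np.asarray(self.depth, dtype=np.int32)
        self.leaf_id = np.asarray(self.leaf_id, dtype=np.int32)

    def uses(self, var: int) -> bool:
        return bool(np.any(self.feature == var))

    def assign_leaves(
        self,
        X: np.ndarray,
        rows: np.ndarray | None = None,
        override: tuple[int, np.ndarray] | None = None,
    ) -> np.ndarray:
        """Vectorized traversal: leaf row index for each subject.

        ``rows`` restricts traversal to those rows of ``X``; ``override``
        replaces one column with alternative (e.g. permuted) values during
        traversal without copying the matrix.
        """
        m = len(rows) if rows is not None else len(X)
        node = np.zeros(m, dtype=np.int32)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                break
            idx = np.flatnonzero(active)
            f = feat[idx]
            src = rows[idx] if rows is not None else idx
            vals = X[src, f]
            if override is not None:
                var, repl = override
                hit = f == var
                if hit.any():
                    vals = vals.copy()
                    vals[hit] = repl[idx[hit]]
            go_left = vals <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.left[node[idx]], self.right[node[idx]]
            )
        return self.leaf_id[node]

    def assign_leaves_tracking(
        self, X: np.ndarray, rows: np.ndarray, n_vars: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Leaf assignment plus a per-row bitmask of variables on the path."""
        m = len(rows)
        words = (n_vars + 63) // 64
        mask = np.zeros((m, words), dtype=np.uint64)
        node = np.zeros(m, dtype=np.int32)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                break
            idx = np.flatnonzero(active)
            f = feat[idx]
            np.bitwise_or.at(
                mask,
                (idx, f // 64),
                np.uint64(1) << (f % 64).astype(np.uint64),
            )
            go_left = X[rows[idx], f] <= self.threshold[node[idx]]
            node[idx] = np.where(
                go_left, self.left[node[idx]], self.right[node[idx]]
            )
        return self.leaf_id[node], mask


# ----------------------------------------------------------------------
# Log-rank split statistic
# ----------------------------------------------------------------------

def logrank_split_statistic(
    times: np.ndarray, events: np.ndarray, group_indicator: np.ndarray
) -> float:
    """|standardized two-sample log-rank statistic| for one candidate split.

    ``group_indicator`` is boolean (True = left daughter).  At each distinct
    event time the observed number of left-daughter events is compared with
    its hypergeometric expectation given the at-risk counts; the statistic
    is |sum(O - E)| / sqrt(sum Var).  Returns 0 when the variance vanishes
    (e.g. one daughter empty at all event times).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    g = np.asarray(group_indicator, dtype=bool)
    if g.all() or not g.any():
        return 0.0
    num, var = _logrank_terms(times, events, g[:, None])
    if var[0] <= 0:
        return 0.0
    return float(abs(num[0]) / np.sqrt(var[0]))


def _logrank_terms(
    times: np.ndarray,
    events: np.ndarray,
    membership: np.ndarray,
    assume_sorted: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched log-rank numerator & variance for candidate memberships.

    ``membership`` is (m, C) boolean; rows must correspond to ``times``.
    Handles tied event times by grouping (Breslow-style d/Y increments).
    ``assume_sorted`` skips the time sort when rows are already ascending.
    """
    if assume_sorted:
        t = np.asarray(times, dtype=float)
        ev = np.asarray(events, dtype=float)
        M = np.asarray(membership, dtype=float)
    else:
        order = np.argsort(times, kind="stable")
        t = times[order]
        ev = events[order].astype(float)
        M = np.asarray(membership, dtype=float)[order]
    m = len(t)
    ev_rows = np.flatnonzero(ev > 0)
    if len(ev_rows) == 0:
        C = M.shape[1]
        return np.zeros(C), np.zeros(C)
    te = t[ev_rows]
    new_grp = np.empty(len(te), dtype=bool)
    new_grp[0] = True
    new_grp[1:] = te[1:] != te[:-1]
    gstart = np.flatnonzero(new_grp)  # positions into ev_rows
    tdist = te[gstart]  # distinct event times
    first_row = np.searchsorted(t, tdist, side="left")
    Y = (m - first_row).astype(float)
    # group-1 at-risk counts: suffix sums of segment sums between event times
    if first_row[0] != 0:
        bounds = np.concatenate(([0], first_row))
        seg = np.add.reduceat(M, bounds, axis=0)[1:]
    else:
        seg = np.add.reduceat(M, first_row, axis=0)
    Y1 = np.cumsum(seg[::-1], axis=0)[::-1]
    d = np.add.reduceat(ev[ev_rows], gstart)
    d1 = np.add.reduceat(M[ev_rows], gstart, axis=0)
    frac = Y1 / Y[:, None]
    num = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(Y > 1, (Y - d) / (Y - 1), 0.0)
    var = (d[:, None] * frac * (1.0 - frac) * corr[:, None]).sum(axis=0)
    return num, var


# ----------------------------------------------------------------------
# Forest
# ----------------------------------------------------------------------

class SurvivalForest:
    """Bootstrap ensemble of log-rank-split survival trees."""

    def __init__(self, config: ForestConfig):
        self.config = config
        self.trees_: list[_Tree] = []
        self.var_names_: list[str] = []
        self.grid_: np.ndarray | None = None
        self._X: np.ndarray | None = None
        self._time: np.ndarray | None = None
        self._event: np.ndarray | None = None

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        time: np.ndarray,
        event: np.ndarray,
        var_names: Sequence[str] | None = None,
    ) -> "SurvivalForest":
        X = np.ascontiguousarray(np.asarray(X, dtype=float))
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=np.int8)
        n, p = X.shape
        if event.sum() < 2:
            raise FitError("need at least 2 events to grow a survival forest")
        self.var_names_ = (
            list(var_names) if var_names is not None else [f"x{j}" for j in range(p)]
        )
        if len(self.var_names_) != p:
            raise ConfigurationError("var_names length mismatch")
        self._X, self._time, self._event = X, time, event
        self.grid_ = np.unique(time[event == 1])
        cfg = self.config
        mtry = cfg.mtry or int(np.ceil(np.sqrt(p)))
        mtry = min(mtry, p)
        rng = np.random.default_rng(cfg.seed)
        self.trees_ = [
            self._grow_tree(X, time, event, mtry, rng) for _ in range(cfg.n_trees)
        ]
        self._oob_cache = None
        return self

    def _grow_tree(
        self,
        X: np.ndarray,
        time: np.ndarray,
        event: np.ndarray,
        mtry: int,
        rng: np.random.Generator,
    ) -> _Tree:
        n, p = X.shape
        cfg = self.config
        inbag = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[inbag] = False
        tree = _Tree()
        tree.inbag = inbag
        tree.oob = np.flatnonzero(oob_mask)
        tree.first_split_depth = np.full(p, -1, dtype=np.int32)

        leaf_members: list[np.ndarray] = []
        # iterative growth with an explicit stack; node index sets are kept
        # sorted by time (boolean-mask splits preserve the order), so the
        # log-rank evaluation never re-sorts
        root = tree.new_node(0)
        inbag_sorted = inbag[np.argsort(time[inbag], kind="stable")]
        stack = [(root, inbag_sorted, 0)]
        while stack:
            node, idx, depth = stack.pop()
            split = None
            if cfg.max_depth is None or depth < cfg.max_depth:
                split = self._best_split(X, time, event, idx, mtry, rng)
            if split is None:
                tree.leaf_id[node] = len(leaf_members)
                leaf_members.append(idx)
                continue
            var, thr = split
            tree.feature[node] = var
            tree.threshold[node] = thr
            if tree.first_split_depth[var] < 0:
                tree.first_split_depth[var] = depth
            go_left = X[idx, var] <= thr
            left = tree.new_node(depth + 1)
            right = tree.new_node(depth + 1)
            tree.left[node] = left
            tree.right[node] = right
            stack.append((left, idx[go_left], depth + 1))
            stack.append((right, idx[~go_left], depth + 1))
        tree.finalize()
        tree.leaf_chf = self._leaf_chfs(leaf_members, time, event)
        return tree

    def _best_split(
        self,
        X: np.ndarray,
        time: np.ndarray,
        event: np.ndarray,
        idx: np.ndarray,
        mtry: int,
        rng: np.random.Generator,
    ) -> tuple[int, float] | None:
        cfg = self.config
        ev = event[idx]
        n_ev = int(ev.sum())
        if n_ev < 2 * cfg.min_events or len(idx) < 2:
            return None
        p = X.shape[1]
        m = len(idx)
        cand_vars = rng.choice(p, size=min(mtry, p), replace=False)
        Xn = X[np.ix_(idx, cand_vars)]
        # candidate thresholds: up to nsplit random distinct cut points per
        # variable (drawn from observed values; small nodes scanned in full)
        cols: list[int] = []
        thrs: list[float] = []
        for c in range(len(cand_vars)):
            col = Xn[:, c]
            pool = col if m <= 256 else col[rng.integers(0, m, 128)]
            vals = np.unique(pool)
            if len(vals) < 2:
                continue
            # interior cut points; splitting sends x <= t to the left
            cuts = vals[:-1]
            if len(cuts) > cfg.nsplit:
                cuts = rng.choice(cuts, size=cfg.nsplit, replace=False)
            cols.extend([c] * len(cuts))
            thrs.extend(cuts.tolist())
        if not cols:
            return None
        cols_a = np.asarray(cols)
        thrs_a = np.asarray(thrs)
        M = Xn[:, cols_a] <= thrs_a  # (m, C)
        # admissibility: both daughters keep >= min_events events
        ev_left = M[ev > 0].sum(axis=0)
        ok = (ev_left >= cfg.min_events) & (n_ev - ev_left >= cfg.min_events)
        if not ok.any():
            return None
        num, var = _logrank_terms(time[idx], ev, M[:, ok], assume_sorted=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(var > 0, np.abs(num) / np.sqrt(var), -np.inf)
        if not np.any(stat > -np.inf):
            return None
        best = int(np.argmax(stat))
        if stat[best] <= 0:
            return None
        sel = np.flatnonzero(ok)[best]
        return int(cand_vars[cols_a[sel]]), float(thrs_a[sel])

    def _leaf_chfs(
        self, leaf_members: list[np.ndarray], time: np.ndarray, event: np.ndarray
    ) -> np.ndarray:
        grid = self.grid_
        out = np.zeros((len(leaf_members), len(grid)))
        for i, idx in enumerate(leaf_members):
            out[i] = nelson_aalen_on_grid(time[idx], event[idx], grid)
        return out

    # -- prediction ----------------------------------------------------
    def ensemble_chf(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ensemble cumulative hazard for new subjects.

        Returns ``(grid, chf)`` where ``chf[i, k]`` is the average over all
        trees of the terminal-node Nelson-Aalen estimator at ``grid[k]``.
        """
        X_new = np.asarray(X_new, dtype=float)
        if not np.all(np.isfinite(X_new)):
            raise ValueError("covariates must be complete for prediction")
        acc = np.zeros((len(X_new), len(self.grid_)))
        for tree in self.trees_:
            acc += tree.leaf_chf[tree.assign_leaves(X_new)]
        return self.grid_, acc / len(self.trees_)

    def predicted_incidence(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predicted cumulative incidence 1 - exp(-ensemble CHF)."""
        grid, chf = self.ensemble_chf(X_new)
        return grid, 1.0 - np.exp(-chf)

    def mortality(self, X_new: np.ndarray) -> np.ndarray:
        """Ensemble mortality: CHF summed over the event-time grid."""
        _, chf = self.ensemble_chf(X_new)
        return chf.sum(axis=1)

    # -- OOB machinery -------------------------------------------------
    def _oob_leaf_mortality(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached per-tree OOB mortality contributions.

        Returns (risk_sum, count) arrays of length n: total and number of
        OOB tree mortalities per subject.
        """
        if getattr(self, "_oob_cache", None) is None:
            n = len(self._time)
            risk = np.zeros(n)
            count = np.zeros(n)
            self._tree_oob_mort = []
            self._tree_mort = []
            self._tree_path_mask = []
            p = len(self.var_names_)
            for tree in self.trees_:
                mort = tree.leaf_chf.sum(axis=1)
                self._tree_mort.append(mort)
                leaves, mask = tree.assign_leaves_tracking(self._X, tree.oob, p)
                self._tree_path_mask.append(mask)
                contrib = mort[leaves]
                self._tree_oob_mort.append(contrib)
                risk[tree.oob] += contrib
                count[tree.oob] += 1
            self._oob_cache = (risk, count)
        return self._oob_cache

    def oob_mortality(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject OOB ensemble mortality and the valid-subject mask."""
        risk, count = self._oob_leaf_mortality()
        valid = count > 0
        out = np.full(len(risk), np.nan)
        out[valid] = risk[valid] / count[valid]
        return out, valid

    def oob_cindex(self) -> float:
        """Harrell concordance of OOB ensemble mortality with outcome."""
        risk, valid = self.oob_mortality()
        if not valid.all():
            warnings.warn(
                f"{(~valid).sum()} subjects never out-of-bag; excluded from "
                "the OOB concordance",
                stacklevel=2,
            )
        return harrell_cindex(
            self._time[valid], self._event[valid], risk[valid]
        )

    # -- variable ranking ----------------------------------------------
    def minimal_depth(self) -> pd.Series:
        """Mean-over-trees minimal depth per variable (root = 0).

        A variable never used in a tree contributes that tree's maximal
        depth + 1, which keeps the ranking a total order.
        """
        p = len(self.var_names_)
        acc = np.zeros(p)
        for tree in self.trees_:
            d = tree.first_split_depth.astype(float).copy()
            d[d < 0] = tree.max_depth + 1
            acc += d
        return pd.Series(acc / len(self.trees_), index=self.var_names_)

    def permutation_vimp(
        self, n_reps: int | None = None, seed: int | None = None
    ) -> pd.Series:
        """Permutation VIMP: baseline OOB concordance minus the OOB
        concordance after permuting each variable among every tree's
        out-of-bag subjects (averaged over ``n_reps`` permutations).
        """
        cfg = self.config
        n_reps = n_reps or cfg.vimp_reps
        base_risk, count = self._oob_leaf_mortality()
        valid = count > 0
        t, e = self._time[valid], self._event[valid]
        c0 = harrell_cindex(t, e, base_risk[valid] / count[valid])
        p = len(self.var_names_)
        vimp = np.zeros(p)
        master = np.random.default_rng(
            self.config.seed + 1 if seed is None else seed
        )
        # fixed sub-seed per variable for reproducibility irrespective of
        # evaluation order
        var_seeds = master.integers(0, 2**31 - 1, size=p)
        uses = [set(np.unique(tr.feature[tr.feature >= 0])) for tr in self.trees_]
        for v in range(p):
            rng = np.random.default_rng(var_seeds[v])
            trees_with_v = [k for k, used in enumerate(uses) if v in used]
            if not trees_with_v:
                continue  # variable never split on: permutation changes nothing
            bit = np.uint64(1) << np.uint64(v % 64)
            c_perm = np.empty(n_reps)
            for r in range(n_reps):
                risk = base_risk.copy()
                for k in trees_with_v:
                    tree = self.trees_[k]
                    rows = tree.oob
                    repl = self._X[rows[rng.permutation(len(rows))], v]
                    # only subjects whose baseline path uses v can move
                    touched = (self._tree_path_mask[k][:, v // 64] & bit) != 0
                    if not touched.any():
                        continue
                    sub = np.flatnonzero(touched)
                    leaves = tree.assign_leaves(
                        self._X, rows=rows[sub], override=(v, repl[sub])
                    )
                    risk[rows[sub]] += (
                        self._tree_mort[k][leaves] - self._tree_oob_mort[k][sub]
                    )
                c_perm[r] = harrell_cindex(t, e, risk[valid] / count[valid])
            vimp[v] = c0 - c_perm.mean()
        return pd.Series(vimp, index=self.var_names_)


# ----------------------------------------------------------------------
# Free functions
# ----------------------------------------------------------------------

def nelson_aalen_on_grid(
    time: np.ndarray, event: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at the given time grid."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if len(time) == 0 or event.sum() == 0:
        return np.zeros(len(grid))
    order = np.argsort(time, kind="stable")
    t = time[order]
    ev = event[order].astype(float)
    first = np.r_[True, t[1:] != t[:-1]]
    starts = np.flatnonzero(first)
    d = np.add.reduceat(ev, starts)
    Y = (len(t) - starts).astype(float)
    tt = t[starts]
    keep = d > 0
    increments = d[keep] / Y[keep]
    chf_at_events = np.cumsum(increments)
    pos = np.searchsorted(tt[keep], grid, side="right")
    return np.r_[0.0, chf_at_events][pos]


def harrell_cindex(time: np.ndarray, event: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's c: P(higher risk score fails first) over comparable pairs.

    A pair is comparable when the earlier subject has an event (an event at
    time t vs anyone followed beyond t, or vs a censored subject at t);
    pairs of tied event times are not comparable.  Tied risk scores count
    1/2.  Matches the usual Harrell convention (e.g. lifelines).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    r = np.asarray(risk, dtype=float)
    if e.sum() == 0:
        raise FitError("no comparable pairs: zero events")
    conc = ties = 0.0
    total = 0
    for i in np.flatnonzero(e):
        partners = (t > t[i]) | ((t == t[i]) & ~e)
        m = int(partners.sum())
        if m == 0:
            continue
        rp = r[partners]
        conc += (rp < r[i]).sum()
        ties += (rp == r[i]).sum()
        total += m
    if total == 0:
        raise FitError("no comparable pairs")
    return float((conc + 0.5 * ties) / total)


def design_matrix(
    cohort: Cohort, variables: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix from a cohort for forest fitting.

    Genotypes enter as ordered 0/1/2 dosage (mode-imputed); categorical
    covariates are one-hot encoded; continuous covariates pass through.
    """
    geno = cohort.imputed_genotypes()
    cov = cohort.covariates
    num = cov.select_dtypes(include=[np.number])
    cat = cov.select_dtypes(exclude=[np.number])
    if len(cat.columns):
        cat = pd.get_dummies(cat, dtype=float)
    frame = pd.concat([geno, num, cat], axis=1)
    if variables is not None:
        missing = [v for v in variables if v not in frame.columns]
        if missing:
            raise ConfigurationError(f"unknown variables: {missing}")
        frame = frame[list(variables)]
    if frame.isna().any().any():
        frame = frame.fillna(frame.median(numeric_only=True))
    return frame.to_numpy(dtype=float), list(frame.columns)


def grow_forest(
    cohort: Cohort,
    config: ForestConfig,
    variables: Sequence[str] | None = None,
) -> SurvivalForest:
    """Fit a survival forest on (a subset of) a cohort's variables."""
    X, names = design_matrix(cohort, variables)
    forest = SurvivalForest(config)
    return forest.fit(X, cohort.time_years, cohort.event, names)


def ranking_table(forest: SurvivalForest) -> pd.DataFrame:
    """Per-variable minimal depth, VIMP and their ranks (1 = best)."""
    md = forest.minimal_depth()
    vimp = forest.permutation_vimp()
    table = pd.DataFrame(
        {
            "variable": md.index,
            "minimal_depth": md.to_numpy(),
            "vimp": vimp.to_numpy(),
        }
    )
    table["md_rank"] = table["minimal_depth"].rank(method="first").astype(int)
    table["vimp_rank"] = (-table["vimp"]).rank(method="first").astype(int)
    return table.sort_values("minimal_depth", ignore_index=True)


@dataclass
class NestedModelCurve:
    """OOB error sequence of nested top-k forests plus drop errors.

    ``errors[k]`` is the OOB error of the forest on the top-k variables,
    with ``errors[0] = 0.5`` for the null model by convention, so that
    ``0.5 - errors[k]`` telescopes into the cumulative sum of drop errors.
    """

    variables: list[str]
    errors: np.ndarray  # length K+1, errors[0] = null error 0.5

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors, dtype=float)
        if len(self.errors) != len(self.variables) + 1:
            raise ConfigurationError("errors must have length K+1 (incl. null)")
        if np.any((self.errors < 0) | (self.errors > 1)):
            raise ConfigurationError("errors must lie in [0, 1]")

    @property
    def drop_errors(self) -> np.ndarray:
        return -np.diff(self.errors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "cindex": 1.0 - self.errors[1:],
                "error": self.errors[1:],
                "drop_error": self.drop_errors,
            }
        )


def nested_error_curve(
    cohort: Cohort,
    ordered_variables: Sequence[str],
    config: ForestConfig,
) -> NestedModelCurve:
    """OOB error of forests on the top-k variables, k = 1..K.

    The ordering is typically minimal depth ascending.  The null model
    (k = 0) is assigned error 0.5: with no variables the forest cannot
    order any pair, which is chance-level concordance.
    """
    ordered_variables = list(ordered_variables)
    if not ordered_variables:
        raise ConfigurationError("empty variable ordering")
    errors = [0.5]
    for k in range(1, len(ordered_variables) + 1):
        sub = grow_forest(
            cohort, replace(config, seed=config.seed + k), ordered_variables[:k]
        )
        errors.append(1.0 - sub.oob_cindex())
    return NestedModelCurve(ordered_variables, np.asarray(errors))


def drop_error_rates(curve: NestedModelCurve) -> np.ndarray:
    """Drop errors d_k = e_{k-1} - e_k (may be negative)."""
    return curve.drop_errors
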