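"""Tree-based explanatory modelling of treeline elevation deviation.

Two complementary methods mirror the two-stage analysis the package is
built around:

* :class:`DeviationForest` — a bagged ensemble of regression trees with
  out-of-bag (OOB) permutation variable importance (%IncMSE) and partial
  dependence, used to *rank* the 17 explanatory factors;
* :class:`ConditionalInferenceTree` — recursive partitioning in which a
  split requires a Monte-Carlo-significant association (permutation test
  on the absolute Pearson correlation, Bonferroni-adjusted across
  candidate variables), used to read off interpretable threshold rules.
  The significance requirement replaces pruning: insignificant nodes
  simply stop, which controls over-fitting by construction.

Both estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params``) and are deterministic given ``random_state``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ForestConfig",
    "DeviationForest",
    "ConditionalInferenceTree",
    "CTreeNode",
    "fit_forest",
    "permutation_importance",
    "partial_dependence",
    "fit_ctree",
    "summarize_terminal_nodes",
    "split_features",
    "RESPONSE_COLUMN",
]

RESPONSE_COLUMN = "elevation_deviation"
_ID_COLUMNS = {"point_id", "site_id", "easting", "northing", "elevation",
               "site_max_elevation", "deviation_true"}


def split_features(table: pd.DataFrame, response: str = RESPONSE_COLUMN):
    """Split a feature table into (X, y).

    Explanatory columns are every numeric column that is neither the
    response nor an identifier/coordinate column.
    """
    if response not in table.columns:
        raise ValueError(f"table lacks the response column {response!r}")
    X = table.drop(columns=[response]).select_dtypes("number")
    X = X.drop(columns=[c for c in X.columns if c in _ID_COLUMNS])
    y = table[response]
    if X.isna().any().any() or y.isna().any():
        raise ValueError("feature table contains missing values")
    return X, y


# ---------------------------------------------------------------------------
# Random forest: bagged trees with OOB bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForestConfig:
    """Forest settings; ``candidate_vars_per_split=None`` means ceil(p/3)."""

    n_trees: int = 2000
    candidate_vars_per_split: Optional[int] = None
    min_leaf: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class DeviationForest(RegressorMixin, BaseEstimator):
    """Bagged regression trees with out-of-bag error and importance.

    Each tree is grown on a bootstrap resample of the rows with a random
    subset of ``candidate_vars_per_split`` variables considered at every
    split (default ceil(p/3), the regression-forest convention). The
    bootstrap and OOB bookkeeping are explicit so that per-tree OOB
    permutation importance (%IncMSE) is available.

    Attributes
    ----------
    oob_prediction_ : ndarray
        Per-row mean prediction over trees for which the row was OOB.
    oob_r2_ : float
        R-squared of the OOB predictions against the training response.
    """

    def __init__(
        self,
        n_trees: int = 2000,
        candidate_vars_per_split: Optional[int] = None,
        min_leaf: int = 5,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.candidate_vars_per_split = candidate_vars_per_split
        self.min_leaf = min_leaf
        self.random_state = random_state

    def fit(self, X, y) -> "DeviationForest":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if X.isna().any().any() or np.any(~np.isfinite(y)):
            raise ValueError("missing or non-finite values in training data")
        n, p = X.shape
        mtry = self.candidate_vars_per_split or max(1, math.ceil(p / 3))
        if not 1 <= mtry <= p:
            raise ValueError("candidate_vars_per_split must lie in [1, p]")
        rng = np.random.default_rng(self.random_state)
        Xv = X.to_numpy()

        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = p
        self.estimators_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n, dtype=int)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xv[boot], y[boot])
            self.estimators_.append(tree)
            self.oob_masks_.append(oob)
            if oob.any():
                oob_sum[oob] += tree.predict(Xv[oob])
                oob_cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            self.oob_prediction_ = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
        seen = oob_cnt > 0
        ss_res = float(np.sum((y[seen] - self.oob_prediction_[seen]) ** 2))
        ss_tot = float(np.sum((y[seen] - y[seen].mean()) ** 2))
        self.oob_r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        self._train_X = Xv
        self._train_y = y
        return self

    def predict(self, X) -> np.ndarray:
        Xv = pd.DataFrame(X).to_numpy()
        out = np.zeros(len(Xv))
        for tree in self.estimators_:
            out += tree.predict(Xv)
        return out / len(self.estimators_)

    # -- importance ---------------------------------------------------------

    def permutation_importance(self) -> pd.DataFrame:
        """OOB permutation importance (%IncMSE) per variable.

        For each tree, the OOB MSE is recomputed after shuffling one
        variable among the tree's OOB rows; %IncMSE is the mean over
        trees of the relative MSE increase x100. Returns a DataFrame
        (variable, pct_inc_mse, rank) sorted by descending importance.
        """
        X, y = self._train_X, self._train_y
        p = X.shape[1]
        rng = np.random.default_rng(self.random_state + 1)
        inc = np.zeros(p)
        used = 0
        for tree, oob in zip(self.estimators_, self.oob_masks_):
            if not oob.any():
                continue
            Xo, yo = X[oob], y[oob]
            base = float(np.mean((yo - tree.predict(Xo)) ** 2))
            if base == 0.0:
                continue
            used += 1
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                mse = float(np.mean((yo - tree.predict(Xp)) ** 2))
                inc[j] += (mse - base) / base * 100.0
        if used == 0:
            raise RuntimeError("no usable OOB samples for importance")
        inc /= used
        out = pd.DataFrame(
            {"variable": self.feature_names_in_, "pct_inc_mse": inc}
        ).sort_values("pct_inc_mse", ascending=False, ignore_index=True)
        out["rank"] = np.arange(1, p + 1)
        return out

    # -- partial dependence -------------------------------------------------

    def partial_dependence(self, variable: str, grid_size: int = 25) -> pd.DataFrame:
        """Partial-dependence curve of one variable.

        The grid is quantile-spaced over the training values (robust to
        the stress indices' skew); at each grid value the variable is
        clamped to that value for every training row and the mean
        ensemble prediction recorded.
        """
        names = list(self.feature_names_in_)
        if variable not in names:
            raise ValueError(f"unknown variable {variable!r}")
        j = names.index(variable)
        x = self._train_X[:, j]
        grid = np.unique(np.quantile(x, np.linspace(0, 1, grid_size)))
        Xw = self._train_X.copy()
        means = []
        for v in grid:
            Xw[:, j] = v
            means.append(float(self.predict(Xw).mean()))
        return pd.DataFrame(
            {"variable": variable, "grid_value": grid, "mean_prediction": means}
        )


def fit_forest(table: pd.DataFrame, config: ForestConfig = ForestConfig()):
    """Fit :class:`DeviationForest` on a treeline feature table.

    Returns the fitted forest; its ``oob_r2_`` attribute reports the
    out-of-bag share of response variance explained.
    """
    X, y = split_features(table)
    if len(X) < 50:
        raise ValueError("forest fitting requires at least 50 rows")
    forest = DeviationForest(
        n_trees=config.n_trees,
        candidate_vars_per_split=config.candidate_vars_per_split,
        min_leaf=config.min_leaf,
        random_state=config.seed,
    )
    return forest.fit(X, y)


def permutation_importance(forest: DeviationForest, table=None) -> pd.DataFrame:
    """OOB %IncMSE importance table for a fitted forest."""
    return forest.permutation_importance()


def partial_dependence(
    forest: DeviationForest, table, variable: str, grid_size: int = 25
) -> pd.DataFrame:
    """Partial-dependence curve of ``variable`` from a fitted forest."""
    return forest.partial_dependence(variable, grid_size=grid_size)


# ---------------------------------------------------------------------------
# Conditional inference tree
# ---------------------------------------------------------------------------


@dataclass
class CTreeNode:
    """One node of a fitted conditional inference tree."""

    node_id: int
    n: int
    median: float
    depth: int
    p_adjusted: Optional[float] = None
    split_var: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["CTreeNode"] = None
    right: Optional["CTreeNode"] = None
    indices: Optional[np.ndarray] = None  # terminal nodes only

    @property
    def is_terminal(self) -> bool:
        return self.split_var is None

    def to_dict(self) -> dict:
        d = {"node_id": self.node_id, "n": self.n, "median": self.median}
        if self.is_terminal:
            d["terminal"] = True
        else:
            d.update(
                terminal=False,
                split_var=self.split_var,
                threshold=self.threshold,
                p_adjusted=self.p_adjusted,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


class ConditionalInferenceTree(RegressorMixin, BaseEstimator):
    """Recursive partitioning gated by Monte-Carlo permutation tests.

    At each node, every candidate variable's absolute Pearson correlation
    with the response is compared against its permutation null
    (``n_permutations`` random relabellings of the response, shared
    across variables); per-variable p-values are Bonferroni-adjusted
    across the candidates. If no adjusted p-value falls below ``alpha``
    the node is terminal; otherwise the node splits on the smallest-p
    variable at the threshold maximising the between-group difference in
    mean response, subject to ``min_node`` observations on each side.

    ``predict`` returns the terminal-node median (the node statistic the
    analysis reports).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 9999,
        min_node: int = 20,
        max_depth: Optional[int] = None,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.min_node = min_node
        self.max_depth = max_depth
        self.random_state = random_state

    # -- node-level machinery ----------------------------------------------

    def _association_test(self, X: np.ndarray, y: np.ndarray, rng):
        """Permutation p-values of |Pearson r| for each column of X.

        Returns (p_values, abs_r); columns with zero variance get p=1.
        """
        n, p = X.shape
        sx = X.std(axis=0)
        live = sx > 0
        p_vals = np.ones(p)
        abs_r = np.zeros(p)
        if not live.any() or y.std() == 0:
            return p_vals, abs_r
        Xn = np.zeros_like(X)
        Xn[:, live] = (X[:, live] - X[:, live].mean(axis=0)) / (
            sx[live] * math.sqrt(n)
        )
        yn = (y - y.mean()) / (y.std() * math.sqrt(n))
        r_obs = np.abs(yn @ Xn)  # length p; zero for dead columns
        abs_r = r_obs
        B = self.n_permutations
        exceed = np.zeros(p)
        chunk = 1000
        done = 0
        while done < B:
            b = min(chunk, B - done)
            P = rng.permuted(np.tile(yn, (b, 1)), axis=1)
            R = np.abs(P @ Xn)  # (b, p)
            exceed += (R >= r_obs - 1e-12).sum(axis=0)
            done += b
        p_vals = (1.0 + exceed) / (B + 1.0)
        p_vals[~live] = 1.0
        return p_vals, abs_r

    def _best_threshold(self, x: np.ndarray, y: np.ndarray):
        """Cutpoint maximising |mean(left) - mean(right)| with both sides
        holding at least ``min_node`` observations; None if no valid cut."""
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        n = len(xs)
        csum = np.cumsum(ys)
        total = csum[-1]
        k = np.arange(1, n)  # left-group sizes
        mean_l = csum[:-1] / k
        mean_r = (total - csum[:-1]) / (n - k)
        valid = (k >= self.min_node) & (n - k >= self.min_node)
        valid &= xs[:-1] < xs[1:]  # cut only between distinct values
        if not valid.any():
            return None
        gap = np.abs(mean_l - mean_r)
        gap[~valid] = -np.inf
        i = int(np.argmax(gap))
        return float((xs[i] + xs[i + 1]) / 2.0)

    def _grow(self, X, y, idx, depth, rng) -> CTreeNode:
        node = CTreeNode(
            node_id=self._next_id,
            n=len(idx),
            median=float(np.median(y[idx])),
            depth=depth,
        )
        self._next_id += 1
        stop = (
            len(idx) < 2 * self.min_node
            or (self.max_depth is not None and depth >= self.max_depth)
            or np.std(y[idx]) == 0
        )
        if not stop:
            p_vals, abs_r = self._association_test(X[idx], y[idx], rng)
            m = int(np.sum(X[idx].std(axis=0) > 0))
            p_adj = np.minimum(p_vals * max(m, 1), 1.0)
            # smallest adjusted p; ties broken by the stronger association
            best = min(range(X.shape[1]), key=lambda j: (p_adj[j], -abs_r[j]))
            if p_adj[best] < self.alpha:
                thr = self._best_threshold(X[idx, best], y[idx])
                if thr is not None:
                    left = idx[X[idx, best] <= thr]
                    right = idx[X[idx, best] > thr]
                    node.split_var = self._names[best]
                    node.threshold = thr
                    node.p_adjusted = float(p_adj[best])
                    node.left = self._grow(X, y, left, depth + 1, rng)
                    node.right = self._grow(X, y, right, depth + 1, rng)
                    return node
        node.indices = idx
        return node

    # -- sklearn surface ----------------------------------------------------

    def fit(self, X, y) -> "ConditionalInferenceTree":
        Xdf = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if Xdf.isna().any().any() or np.any(~np.isfinite(y)):
            raise ValueError("missing or non-finite values in training data")
        if len(Xdf) < 2 * self.min_node:
            raise ValueError("need at least 2*min_node rows to consider a split")
        self._names = [str(c) for c in Xdf.columns]
        self.feature_names_in_ = np.asarray(Xdf.columns)
        self.n_features_in_ = Xdf.shape[1]
        rng = np.random.default_rng(self.random_state)
        self._next_id = 1
        self.tree_ = self._grow(
            Xdf.to_numpy(dtype=float), y, np.arange(len(Xdf)), 0, rng
        )
        self._train_y = y
        return self

    def _route(self, node: CTreeNode, row: np.ndarray) -> CTreeNode:
        while not node.is_terminal:
            j = self._names.index(node.split_var)
            node = node.left if row[j] <= node.threshold else node.right
        return node

    def apply(self, X) -> np.ndarray:
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        return np.array([self._route(self.tree_, row).node_id for row in Xv])

    def predict(self, X) -> np.ndarray:
        Xv = pd.DataFrame(X).to_numpy(dtype=float)
        return np.array([self._route(self.tree_, row).median for row in Xv])

    # -- introspection ------------------------------------------------------

    def terminal_nodes(self) -> list[CTreeNode]:
        out: list[CTreeNode] = []

        def walk(node: CTreeNode):
            if node.is_terminal:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.tree_)
        return out

    def rule_path(self, node_id: int) -> str:
        """The conjunction of inequalities leading to a node."""

        def walk(node: CTreeNode, rules: list[str]):
            if node.node_id == node_id:
                return rules
            if node.is_terminal:
                return None
            lhs = walk(node.left, rules + [f"{node.split_var} <= {node.threshold:g}"])
            if lhs is not None:
                return lhs
            return walk(node.right, rules + [f"{node.split_var} > {node.threshold:g}"])

        rules = walk(self.tree_, [])
        if rules is None:
            raise ValueError(f"no node with id {node_id}")
        return " and ".join(rules) if rules else "(root)"

    def to_json(self, **kw) -> str:
        return json.dumps({"alpha": self.alpha, "tree": self.tree_.to_dict()}, **kw)

    def render_text(self) -> str:
        lines: list[str] = []

        def walk(node: CTreeNode, indent: int):
            pad = "  " * indent
            if node.is_terminal:
                lines.append(
                    f"{pad}[{node.node_id}] n={node.n} median={node.median:.1f}"
                )
            else:
                lines.append(
                    f"{pad}[{node.node_id}] {node.split_var} <= {node.threshold:g} "
                    f"(p_adj={node.p_adjusted:.4f}, n={node.n})"
                )
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.tree_, 0)
        return "\n".join(lines)


def fit_ctree(
    table: pd.DataFrame,
    alpha: float = 0.05,
    n_permutations: int = 9999,
    min_node: int = 20,
    seed: int = 0,
) -> ConditionalInferenceTree:
    """Fit a :class:`ConditionalInferenceTree` on a treeline feature table."""
    X, y = split_features(table)
    tree = ConditionalInferenceTree(
        alpha=alpha,
        n_permutations=n_permutations,
        min_node=min_node,
        random_state=seed,
    )
    return tree.fit(X, y)


def summarize_terminal_nodes(
    tree: ConditionalInferenceTree, table: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """One row per terminal node: id, n, median deviation, rule path."""
    rows = []
    for node in tree.terminal_nodes():
        rows.append(
            {
                "node_id": node.node_id,
                "n": node.n,
                "median_deviation": node.median,
                "rule": tree.rule_path(node.node_id),
            }
        )
    return pd.DataFrame(rows)
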