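"""Monte-Carlo variable-importance ranking and Top-10-Rate selection.

A variable's importance is measured two ways within a regression forest:

* **%IncMSE** — the percent increase in out-of-bag (OOB) mean squared error
  when that variable's values are permuted (permutation importance);
* **node purity** — the total decrease in node impurity (variance, the
  regression analogue of the Gini criterion) contributed by splits on the
  variable.

Because a single ranking is noisy, the ranking is repeated over Monte-Carlo
row subsamples (100 draws of 50% of the rows, without replacement, by
default).  A variable's **Top-10 Rate** is the fraction of draws in which it
ranks among the 10 most important by %IncMSE; variables with a high rate are
*consistently* important, not just occasionally.

scikit-learn's forest does not expose per-tree OOB bookkeeping, so a small
bagged ensemble of decision trees is built here with explicit bootstrap
indices, giving exact control over the OOB permutation measure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "ImportanceTable",
    "importance_once",
    "top10_rate",
    "select_top",
]

logger = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    """Per-variable importance summary over Monte-Carlo draws.

    ``table`` columns: variable, top10_rate, mean_pct_inc_mse,
    mean_node_purity.  ``rank_counts[v][r]`` counts draws in which variable
    v had rank r (1 = most important by %IncMSE).
    """

    table: pd.DataFrame
    rank_counts: pd.DataFrame
    n_draws: int
    k: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class _BaggedForest:
    """Regression bagging with explicit OOB index bookkeeping."""

    def __init__(self, n_trees, mtry, min_leaf, rng):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_leaf = min_leaf
        self.rng = rng
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_idx: list[np.ndarray] = []

    def fit(self, X, y):
        n = len(y)
        for _ in range(self.n_trees):
            boot = self.rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=self.mtry,
                min_samples_leaf=self.min_leaf,
                random_state=int(self.rng.integers(0, 2**31)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_idx.append(oob)
        return self

    def oob_mse(self, X, y, permute_col=None, rng=None):
        """Aggregate-OOB MSE, optionally with one column permuted."""
        n = len(y)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_idx):
            if len(oob) == 0:
                continue
            Xo = X[oob]
            if permute_col is not None:
                Xo = Xo.copy()
                Xo[:, permute_col] = rng.permutation(Xo[:, permute_col])
            sums[oob] += tree.predict(Xo)
            counts[oob] += 1
        have = counts > 0
        pred = sums[have] / counts[have]
        return float(np.mean((y[have] - pred) ** 2))

    def node_purity(self, p):
        """Total impurity decrease per feature, summed over trees (scaled by
        each tree's training size — the regression IncNodePurity analogue)."""
        total = np.zeros(p)
        for tree in self.trees:
            imp = tree.tree_.compute_feature_importances(normalize=False)
            total += imp * tree.tree_.n_node_samples[0]
        return total / len(self.trees)


def importance_once(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    seed: int = 0,
    n_trees: int = 100,
    min_leaf: int = 5,
    mtry: int | None = None,
) -> pd.DataFrame:
    """One seeded forest fit and its per-variable importance.

    Returns a frame with columns ``variable``, ``pct_inc_mse`` (percent OOB
    MSE increase under permutation), ``node_purity``, sorted by
    ``pct_inc_mse`` descending.  Constant covariates get importance 0 with a
    warning.
    """
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    X = df[list(covariates)].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    p = len(covariates)
    constant = [c for j, c in enumerate(covariates) if len(np.unique(X[:, j])) == 1]
    if constant:
        warnings.warn(f"constant covariates have importance 0: {constant}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    forest = _BaggedForest(
        n_trees=n_trees, mtry=mtry or max(1, p // 3), min_leaf=min_leaf, rng=rng
    ).fit(X, y)
    base = forest.oob_mse(X, y)
    perm_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed + 1))
    inc = np.zeros(p)
    for j in range(p):
        if covariates[j] in constant:
            continue
        mse_p = forest.oob_mse(X, y, permute_col=j, rng=perm_rng)
        inc[j] = 100.0 * (mse_p - base) / base if base > 0 else 0.0
    out = pd.DataFrame(
        {
            "variable": covariates,
            "pct_inc_mse": inc,
            "node_purity": forest.node_purity(p),
        }
    )
    return out.sort_values("pct_inc_mse", ascending=False).reset_index(drop=True)


def top10_rate(
    df: pd.DataFrame,
    covariates: list[str],
    outcome: str = "lrm50",
    *,
    n_draws: int = 100,
    frac: float = 0.5,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    replace: bool = False,
    stratify_by_participant: bool = False,
    **forest_kwargs,
) -> ImportanceTable:
    """Monte-Carlo Top-k membership rates over row subsamples.

    Each draw takes ``frac`` of the rows (without replacement by default,
    optionally stratified by participant), reruns the forest importance, and
    tallies which variables land in the top ``k`` by %IncMSE.  Fully seeded
    and reproducible.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not (0.0 < frac <= 1.0):
        raise ValueError("frac must lie in (0, 1]")
    p = len(covariates)
    if p < k:
        warnings.warn(f"only {p} covariates; clipping k from {k}")
        k = p
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    top_counts = pd.Series(0, index=covariates, dtype=int)
    inc_sums = pd.Series(0.0, index=covariates)
    purity_sums = pd.Series(0.0, index=covariates)
    ranks = pd.DataFrame(0, index=covariates, columns=range(1, p + 1))
    for d in range(n_draws):
        if stratify_by_participant and "participant" in df.columns:
            sub = df.groupby("participant", group_keys=False).apply(
                lambda g: g.sample(
                    n=max(1, int(round(frac * len(g)))),
                    replace=replace,
                    random_state=int(rng.integers(0, 2**31)),
                ),
                include_groups=True,
            )
        else:
            n_sub = max(2, int(round(frac * len(df))))
            idx = (
                rng.integers(0, len(df), size=n_sub)
                if replace
                else rng.choice(len(df), size=n_sub, replace=False)
            )
            sub = df.iloc[idx]
        imp = importance_once(
            sub,
            covariates,
            outcome,
            seed=int(rng.integers(0, 2**31)),
            n_trees=n_trees,
            **forest_kwargs,
        )
        for r, var in enumerate(imp["variable"], start=1):
            ranks.loc[var, r] += 1
        top_counts[imp["variable"].iloc[:k]] += 1
        inc_sums += imp.set_index("variable")["pct_inc_mse"]
        purity_sums += imp.set_index("variable")["node_purity"]
    table = pd.DataFrame(
        {
            "variable": covariates,
            "top10_rate": (top_counts / n_draws).to_numpy(),
            "mean_pct_inc_mse": (inc_sums / n_draws).to_numpy(),
            "mean_node_purity": (purity_sums / n_draws).to_numpy(),
        }
    ).sort_values(
        ["top10_rate", "mean_pct_inc_mse", "variable"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    return ImportanceTable(table=table, rank_counts=ranks, n_draws=n_draws, k=k)


def select_top(table: ImportanceTable, k: int = 10) -> list[str]:
    """Top-k variables by Top-10 Rate; ties broken by mean %IncMSE, then
    name (deterministic)."""
    t = table.table.sort_values(
        ["top10_rate", "mean_pct_inc_mse", "variable"],
        ascending=[False, False, True],
    )
    return t["variable"].iloc[:k].tolist()
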