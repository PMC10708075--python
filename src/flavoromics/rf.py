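"""Random-forest Gini importance for compound tables.

Mean decrease in impurity ("Gini importance") from a random-forest
classifier on the replicate x compound relative-content matrix. The forest
itself comes from scikit-learn; this module pins the conventions: a fixed
seed gives identical importances, the raw (unnormalized) per-tree impurity
decreases are averaged and reported alongside a sum-to-1 normalized column,
and ranks break ties stably by compound name.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = ["ImportanceTable", "fit_rf_importance"]


@dataclass
class ImportanceTable:
    """Per-variable Gini importance.

    ``table``: DataFrame indexed by variable name with columns
    ``gini_raw`` (mean unnormalized impurity decrease), ``gini_normalized``
    (sums to 1) and ``rank`` (1 = most important; ties broken by name).
    """

    table: pd.DataFrame
    n_trees: int
    seed: int | None

    @property
    def gini(self) -> pd.Series:
        return self.table["gini_raw"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def fit_rf_importance(
    X,
    y,
    n_trees: int = 500,
    seed: int | None = 0,
    max_features: str | int | float = "sqrt",
) -> ImportanceTable:
    """Fit a random forest and report Gini (impurity-decrease) importance.

    ``X`` may be a DataFrame (column names become variable names) or an
    array. Requires two or more classes with at least 2 samples each in
    total; deterministic for a fixed ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"var_{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("random-forest importance requires >= 2 classes")

    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        bootstrap=True,
    ).fit(Xv, y)

    raw = np.mean(
        [tree.tree_.compute_feature_importances(normalize=False) for tree in forest.estimators_],
        axis=0,
    )
    total = raw.sum()
    norm = raw / total if total > 0 else np.zeros_like(raw)
    tbl = pd.DataFrame(
        {"gini_raw": raw, "gini_normalized": norm},
        index=pd.Index(names, name="compound"),
    )
    order = sorted(range(len(names)), key=lambda i: (-raw[i], names[i]))
    ranks = np.empty(len(names), dtype=int)
    ranks[order] = np.arange(1, len(names) + 1)
    tbl["rank"] = ranks
    return ImportanceTable(table=tbl, n_trees=n_trees, seed=seed)
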