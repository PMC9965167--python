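"""Shallow regression baselines on the handcrafted feature table.

Support vector regression (SVR) and random forest regression (RFR) with an
exhaustive grid search scored by inner 5-fold cross-validated R², evaluated
over repeated stratified shuffles of a 60/20/20 train/validation/test split
("bootstrap" in the reshuffling sense).  Standardization and the search see
the training split only.  Feature-set subsets cover the seven modality
combinations compared in the emulated study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.svm import SVR

from .evaluation import regression_metrics
from .plot_prep import TraitScaler

FEATURE_SETS = (
    "thermal",
    "inten",
    "dsm",
    "hyper",
    "hyper+dsm",
    "hyper+dsm+inten",
    "hyper+dsm+inten+thermal",
)

_MODALITY_PREFIX = {"thermal": ("Tir",), "inten": ("I",), "dsm": ("H",)}


def feature_set_columns(feature_set: str, columns: list[str]) -> list[str]:
    """Resolve a named modality subset to feature-table columns."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}")
    from .features import SPECTRAL_INDEX_REGISTRY

    parts = feature_set.split("+")
    cols: list[str] = []
    for col in columns:
        is_hyper = col in SPECTRAL_INDEX_REGISTRY
        is_thermal = col == "Tir"
        is_height = (not is_hyper and not is_thermal) and col.startswith("H")
        is_inten = (not is_hyper and not is_thermal) and col.startswith("I")
        if ("dsm" in parts and is_height) or ("inten" in parts and is_inten) \
                or ("thermal" in parts and is_thermal) or ("hyper" in parts and is_hyper):
            cols.append(col)
    if not cols:
        raise ValueError(f"feature set {feature_set!r} selects no columns")
    return cols


@dataclass
class SearchSpace:
    """Hyperparameter grids for the two regressors (inner-CV scored)."""

    svr_c: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svr_kernels: tuple[str, ...] = ("rbf", "linear")
    svr_gamma_mult: tuple[float, ...] = (0.1, 1.0, 10.0)  # times the 'scale' heuristic
    svr_epsilon: float = 0.1
    rfr_trees: tuple[int, ...] = (100, 300, 500)
    rfr_depth: tuple = (None, 10, 20)
    rfr_min_leaf: tuple[int, ...] = (1, 3, 5)
    inner_folds: int = 5

    def validate(self) -> None:
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        for name in ("svr_c", "svr_kernels", "rfr_trees", "rfr_depth", "rfr_min_leaf"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} grid is empty")


class ShallowRegressorCV(BaseEstimator, RegressorMixin):
    """SVR or RFR with exhaustive inner-CV grid search, sklearn-style.

    Fitting standardizes features internally (statistics from the fitted X
    only), runs :class:`~sklearn.model_selection.GridSearchCV` scored by R²,
    and refits the best setting on all of X.  Deterministic per
    ``random_state``.
    """

    def __init__(self, regressor: str = "rfr", space: SearchSpace | None = None,
                 random_state: int = 0):
        self.regressor = regressor
        self.space = space
        self.random_state = random_state

    def fit(self, X, y):
        space = self.space or SearchSpace()
        space.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D and aligned with y")
        if len(X) < space.inner_folds:
            raise ValueError("fewer samples than inner folds")
        if np.std(y) == 0:
            raise ValueError("degenerate (constant) target")

        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._sd = sd
        Xs = (X - self._mu) / self._sd

        if self.regressor == "svr":
            gamma_scale = 1.0 / (Xs.shape[1] * Xs.var()) if Xs.var() > 0 else 1.0
            grid = {
                "C": list(space.svr_c),
                "kernel": list(space.svr_kernels),
                "gamma": [m * gamma_scale for m in space.svr_gamma_mult],
            }
            base = SVR(epsilon=space.svr_epsilon)
        elif self.regressor == "rfr":
            grid = {
                "n_estimators": list(space.rfr_trees),
                "max_depth": list(space.rfr_depth),
                "min_samples_leaf": list(space.rfr_min_leaf),
            }
            base = RandomForestRegressor(random_state=self.random_state, n_jobs=1)
        else:
            raise ValueError("regressor must be 'svr' or 'rfr'")

        search = GridSearchCV(base, grid, scoring="r2", cv=space.inner_folds, refit=True)
        search.fit(Xs, y)
        self.search_ = search
        self.best_params_ = search.best_params_
        self.model_ = search.best_estimator_
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.model_.predict((X - self._mu) / self._sd)


def fit_with_search(
    features: pd.DataFrame,
    target: pd.Series,
    regressor: str = "rfr",
    space: SearchSpace | None = None,
    seed: int = 0,
) -> ShallowRegressorCV:
    """Functional wrapper: fit one grid-searched regressor on a feature table."""
    est = ShallowRegressorCV(regressor=regressor, space=space, random_state=seed)
    return est.fit(features.to_numpy(), np.asarray(target, dtype=float))


def mdi_importance(model, feature_names: list[str], top: int = 10) -> pd.Series:
    """Mean-decrease-impurity importances of a fitted forest, descending.

    Accepts a fitted :class:`ShallowRegressorCV` (rfr) or a bare fitted
    forest.  Importances sum to 1.
    """
    forest = getattr(model, "model_", model)
    if not isinstance(forest, RandomForestRegressor) or not hasattr(forest, "feature_importances_"):
        raise TypeError("MDI importance requires a fitted random forest")
    imp = pd.Series(forest.feature_importances_, index=feature_names)
    return imp.sort_values(ascending=False).head(top)


@dataclass
class BootstrapReport:
    """Mean/sd of R², RMSE, MAE per (trait, feature set, regressor, split)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        return (
            self.table.groupby(["trait", "feature_set", "regressor", "split"])
            .agg(["mean", "std"])
            .fillna(0.0)
        )


def stratified_splits(
    index: pd.Index, strata: pd.Series, seed: int, fractions=(0.6, 0.2, 0.2)
):
    """60/20/20 train/val/test split stratified by treatment."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    idx = np.asarray(index)
    strat = np.asarray(strata.loc[index])
    train, rest = train_test_split(
        idx, train_size=fractions[0], stratify=strat, random_state=seed
    )
    rel = fractions[1] / (fractions[1] + fractions[2])
    strat_rest = np.asarray(strata.loc[rest])
    val, test = train_test_split(rest, train_size=rel, stratify=strat_rest, random_state=seed)
    for part, name in ((train, "train"), (val, "val"), (test, "test")):
        if len(part) < 2:
            raise ValueError(f"{name} split has fewer than 2 samples")
    return pd.Index(train), pd.Index(val), pd.Index(test)


def bootstrap_evaluate(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    strata: pd.Series,
    feature_sets=("hyper",),
    regressors=("svr", "rfr"),
    n_shuffles: int = 5,
    space: SearchSpace | None = None,
    seed: int = 0,
) -> BootstrapReport:
    """Repeated-shuffle evaluation of the shallow baselines.

    For each shuffle: a stratified 60/20/20 split; target scaling and the
    hyperparameter search are fit on the training split only; R²/RMSE/MAE are
    recorded on all three splits, in the target's physical units.
    """
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    records = []
    for shuffle in range(n_shuffles):
        split_seed = seed * 1000 + shuffle
        train, val, test = stratified_splits(features.index, strata, split_seed)
        for fs in feature_sets:
            cols = feature_set_columns(fs, list(features.columns))
            for trait in targets.columns:
                y_scaler = TraitScaler().fit(targets[[trait]], fit_rows=train)
                y_std = y_scaler.transform(targets[[trait]])[trait]
                for reg in regressors:
                    est = ShallowRegressorCV(reg, space, random_state=split_seed)
                    est.fit(features.loc[train, cols].to_numpy(), y_std.loc[train].to_numpy())
                    for split_name, rows in (("train", train), ("val", val), ("test", test)):
                        pred_std = est.predict(features.loc[rows, cols].to_numpy())
                        pred = y_scaler.inverse_transform_array(
                            pred_std.reshape(-1, 1)
                        ).ravel()
                        m = regression_metrics(
                            targets.loc[rows, trait].to_numpy(), pred
                        )
                        records.append(
                            {
                                "shuffle": shuffle,
                                "trait": trait,
                                "feature_set": fs,
                                "regressor": reg,
                                "split": split_name,
                                "r2": m["r2"],
                                "rmse": m["rmse"],
                                "mae": m["mae"],
                            }
                        )
    table = pd.DataFrame.from_records(records)
    return BootstrapReport(table=table)


def plot_report(report: BootstrapReport, path: str, split: str = "test") -> None:
    """Bar chart of mean ± sd test R² per trait, feature set and regressor."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = report.table[report.table["split"] == split]
    stats = sub.groupby(["trait", "feature_set", "regressor"])["r2"].agg(["mean", "std"])
    traits = stats.index.get_level_values("trait").unique()
    fig, axes = plt.subplots(len(traits), 1, figsize=(8, 2.5 * len(traits)), squeeze=False)
    for ax, trait in zip(axes.ravel(), traits):
        block = stats.loc[trait]
        labels = [f"{fs}\n{reg}" for fs, reg in block.index]
        ax.bar(labels, block["mean"], yerr=block["std"].fillna(0), capsize=3)
        ax.set_ylabel("R²")
        ax.set_title(trait)
        ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(importances: pd.Series, path: str) -> None:
    """Horizontal bar chart of MDI importances in descending order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.4 * len(importances) + 1))
    imp = importances.sort_values()
    ax.barh(imp.index, imp.to_numpy())
    ax.set_xlabel("mean decrease impurity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
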