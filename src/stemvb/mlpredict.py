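"""Bending-strength prediction from microanatomical traits.

Implements the evaluation protocol: five named feature sets (all 32 traits;
stem-related; vascular-bundle-related; zone-related; the top-five subset),
recursive feature elimination (RFE) ranking, and a registry of regression
families — Ridge, ordinary linear regression, random forest (100 trees,
depth 10), AdaBoost, SVR and a small feed-forward network — scored under
fivefold cross-validation by RMSE and adjusted R². All predictions used in
scoring are out-of-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .traits import TRAIT_NAMES

STEM_TRAITS = ("SZ_A", "SZ_P", "SZ_LA", "SZ_SA", "SZ_LWR")
ZONE_TRAITS = ("EZ_A", "EZ_T", "PZ_A", "PZ_T", "IZ_A", "IZ_T")
VB_TRAITS = (
    "VB_N", "VB_A", "VB_Aave", "VB_D", "VB_AreaRatio",
    "PZ_VB_N", "PZ_VB_A", "PZ_VB_D", "PZ_VB_AreaRatio",
    "IZ_VB_N", "IZ_VB_A", "IZ_VB_D", "IZ_VB_AreaRatio",
    "MOA", "PMOI", "MOIAL", "MOIAS",
    "aveMOA", "avePMOI", "aveMOIAL", "aveMOIAS",
)
TOP5_TRAITS = ("VB_A", "PZ_VB_A", "PZ_T", "PZ_A", "MOA")

#: the five named feature sets of the evaluation protocol
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "all": TRAIT_NAMES,
    "stem": STEM_TRAITS,
    "vb": VB_TRAITS,
    "zone": ZONE_TRAITS,
    "top5": TOP5_TRAITS,
}

DEFAULT_MODELS = ("adaboost", "linear", "rf", "ridge", "svr")
DEFAULT_SEED = 2021


def make_model(name: str, seed: int = DEFAULT_SEED):
    """Instantiate a registered regression model.

    Linear/kernel/network models are wrapped with feature standardisation;
    tree ensembles are scale-invariant and used bare. Hyperparameters are a
    small frozen grid choice: 100 trees of depth 10 for the random forest,
    RBF SVR with C=10, one hidden layer of 64 units for the network.
    """
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("model", est)])
    if name == "ridge":
        return scaled(Ridge(alpha=1.0))
    if name == "linear":
        return scaled(LinearRegression())
    if name == "rf":
        return RandomForestRegressor(n_estimators=100, max_depth=10,
                                     random_state=seed)
    if name == "adaboost":
        return AdaBoostRegressor(n_estimators=100, random_state=seed)
    if name == "svr":
        return scaled(SVR(kernel="rbf", C=10.0, epsilon=0.01))
    if name == "mlp":
        return scaled(MLPRegressor(hidden_layer_sizes=(64,), max_iter=3000,
                                   random_state=seed))
    raise ValueError(f"unknown model {name!r}; registered: "
                     "ridge, linear, rf, adaboost, svr, mlp")


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel-adjusted R²: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R² needs n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rfe_rank(features: pd.DataFrame, target: np.ndarray | pd.Series,
             k: int = 5, estimator: str = "ridge",
             seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Recursive feature elimination down to ``k`` features.

    At each round the base estimator is refit and the feature with the
    smallest importance (|coefficient| on standardised inputs for linear
    models, impurity importance for the forest) is dropped. Returns one row
    per feature with its elimination ``rank`` (1 = kept to the end) and
    ``selected`` flag; the full elimination order is rank-decreasing.
    """
    y = np.asarray(target, dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant target: nothing to rank features against")
    if k > features.shape[1]:
        raise ValueError(f"k={k} exceeds the {features.shape[1]} features")
    X = features.to_numpy(float)
    if estimator == "ridge":
        est = Ridge(alpha=1.0)
        X = StandardScaler().fit_transform(X)
        getter = "coef_"
    elif estimator == "rf":
        est = RandomForestRegressor(n_estimators=100, max_depth=10,
                                    random_state=seed)
        getter = "feature_importances_"
    else:
        raise ValueError("RFE base estimator must be 'ridge' or 'rf'")
    rfe = RFE(est, n_features_to_select=k, step=1, importance_getter=getter)
    rfe.fit(X, y)
    out = pd.DataFrame({
        "trait": list(features.columns),
        "rank": rfe.ranking_,
        "selected": rfe.support_,
    }).sort_values(["rank", "trait"], kind="stable").reset_index(drop=True)
    return out


@dataclass
class PredictionReport:
    """Cross-validated scores for (model, feature set, target) cells.

    ``per_fold`` has columns target, model, feature_set, fold, n_test,
    rmse, adj_r2; ``pooled`` aggregates the out-of-fold predictions into a
    single RMSE, adjusted R² and Pearson correlation per cell. ``folds``
    maps each sample index to its test fold, fixed by ``seed``.
    """

    per_fold: pd.DataFrame
    pooled: pd.DataFrame
    folds: np.ndarray
    seed: int
    cv: int
    predictions: dict = field(default_factory=dict)


def _fold_assignment(n: int, cv: int, seed: int) -> np.ndarray:
    folds = np.empty(n, dtype=int)
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    for i, (_, test) in enumerate(kf.split(np.arange(n))):
        folds[test] = i
    return folds


def evaluate_models(features: pd.DataFrame, target: np.ndarray | pd.Series,
                    models: tuple[str, ...] = DEFAULT_MODELS,
                    feature_sets: dict[str, tuple[str, ...]] | None = None,
                    cv: int = 5, seed: int = DEFAULT_SEED,
                    target_name: str = "BMMax") -> PredictionReport:
    """Score regression models on feature subsets under k-fold CV.

    ``features`` holds at least the union of the requested feature sets
    (default: every registered set present in the columns). Every model is
    trained on cv-1 folds and scored on the held-out fold; pooled metrics
    use the out-of-fold predictions only.
    """
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if feature_sets is None:
        feature_sets = {name: cols for name, cols in FEATURE_SETS.items()
                        if set(cols) <= set(features.columns)}
    folds = _fold_assignment(n, cv, seed)
    if np.bincount(folds).min() < 2:
        raise ValueError("a fold has fewer than 2 samples; reduce cv")

    per_fold_rows, pooled_rows, predictions = [], [], {}
    for set_name, cols in feature_sets.items():
        X = features[list(cols)].to_numpy(float)
        p = X.shape[1]
        for model_name in models:
            oof = np.empty(n)
            for f in range(cv):
                test = folds == f
                model = make_model(model_name, seed)
                model.fit(X[~test], y[~test])
                oof[test] = model.predict(X[test])
                n_test = int(test.sum())
                fold_r2 = r2_score(y[test], oof[test])
                per_fold_rows.append({
                    "target": target_name, "model": model_name,
                    "feature_set": set_name, "fold": f, "n_test": n_test,
                    "rmse": float(np.sqrt(np.mean((y[test] - oof[test]) ** 2))),
                    "adj_r2": (adjusted_r2(fold_r2, n_test, p)
                               if n_test > p + 1 else float("nan")),
                })
            pooled_r2 = r2_score(y, oof)
            pooled_rows.append({
                "target": target_name, "model": model_name,
                "feature_set": set_name,
                "rmse": float(np.sqrt(np.mean((y - oof) ** 2))),
                "r2": pooled_r2,
                "adj_r2": adjusted_r2(pooled_r2, n, p),
                "pearson_r": float(np.corrcoef(y, oof)[0, 1]),
            })
            predictions[(target_name, model_name, set_name)] = oof.copy()
    return PredictionReport(
        per_fold=pd.DataFrame(per_fold_rows),
        pooled=pd.DataFrame(pooled_rows),
        folds=folds, seed=seed, cv=cv, predictions=predictions,
    )


def _signflip_pvalue(diffs: np.ndarray) -> float:
    """Exact paired sign-flip test on fold-wise differences (two-sided)."""
    k = len(diffs)
    obs = abs(diffs.mean())
    signs = np.array(np.meshgrid(*[[1, -1]] * k)).T.reshape(-1, k)
    null = np.abs((signs * diffs).mean(axis=1))
    return float(np.mean(null >= obs - 1e-15))


def compare_feature_sets(report: PredictionReport, model: str = "ridge",
                         target: str | None = None) -> pd.DataFrame:
    """Rank feature sets by pooled adjusted R² for one model.

    Each set is compared against the top-ranked set by paired fold-wise
    RMSE differences with an exact sign-flip significance summary.
    """
    pooled = report.pooled[report.pooled["model"] == model]
    per_fold = report.per_fold[report.per_fold["model"] == model]
    if target is not None:
        pooled = pooled[pooled["target"] == target]
        per_fold = per_fold[per_fold["target"] == target]
    if pooled["feature_set"].nunique() < 2:
        raise ValueError("need at least two feature sets to compare")
    pooled = pooled.sort_values("adj_r2", ascending=False).reset_index(drop=True)
    best = pooled.loc[0, "feature_set"]

    def fold_rmse(fs: str) -> np.ndarray:
        sub = per_fold[per_fold["feature_set"] == fs].sort_values("fold")
        return sub["rmse"].to_numpy()

    best_rmse = fold_rmse(best)
    rows = []
    for i, row in pooled.iterrows():
        diffs = fold_rmse(row["feature_set"]) - best_rmse
        if len(diffs) != len(best_rmse):
            raise ValueError("mismatched folds between feature sets")
        rows.append({
            "rank": i + 1,
            "feature_set": row["feature_set"],
            "adj_r2": row["adj_r2"],
            "rmse": row["rmse"],
            "mean_fold_rmse_diff_vs_best": float(diffs.mean()),
            "signflip_p_vs_best": _signflip_pvalue(diffs) if i > 0 else 1.0,
        })
    return pd.DataFrame(rows)
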