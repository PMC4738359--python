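"""Random-forest predictor importance with permutation significance.

Importance of a predictor is the increase in out-of-bag (OOB) mean
squared error when that predictor is permuted among a tree's OOB cases,
averaged over the forest and expressed as a percentage of the baseline
OOB MSE (%IncMSE).  Significance of each predictor's importance — and of
the model's cross-validated R² — comes from re-fitting on data whose
response has been permuted, with the +1 permutation-p convention.

Individual trees are scikit-learn CART regressors; the bagging, mtry
feature subsampling (one third of the predictors, the regression
default), OOB bookkeeping and permutation accounting are implemented
here so that per-tree OOB errors are directly available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

MAX_SEED = 2**31 - 1


def _encode(X: pd.DataFrame):
    """One-hot encode categoricals; group dummy columns per original variable."""
    X = pd.DataFrame(X)
    cols = []
    groups: dict[str, list[int]] = {}
    mats = []
    j = 0
    for name in X.columns:
        col = X[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=str(name))
            idx = list(range(j, j + dummies.shape[1]))
            mats.append(dummies.to_numpy(dtype=np.float32))
            cols.extend(dummies.columns)
            groups[str(name)] = idx
            j += dummies.shape[1]
        else:
            mats.append(col.to_numpy(dtype=np.float32)[:, None])
            cols.append(str(name))
            groups[str(name)] = [j]
            j += 1
    Xm = np.ascontiguousarray(np.hstack(mats), dtype=np.float32)
    return Xm, list(groups.keys()), groups


def _grow_forest(Xm: np.ndarray, y: np.ndarray, n_trees: int,
                 max_features, seed: int):
    """Bagged CART trees; returns [(fitted tree, oob index array), ...]."""
    rng = np.random.RandomState(int(seed) % MAX_SEED)
    n = Xm.shape[0]
    forest = []
    for _ in range(n_trees):
        idx = rng.randint(0, n, n)
        est = DecisionTreeRegressor(
            max_features=max_features, random_state=rng.randint(0, MAX_SEED)
        )
        est.fit(Xm[idx], y[idx], check_input=False)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        forest.append((est, np.nonzero(oob)[0]))
    return forest


def _forest_predict(forest, Xq: np.ndarray) -> np.ndarray:
    Xq = np.ascontiguousarray(Xq, dtype=np.float32)
    acc = np.zeros(Xq.shape[0])
    for est, _ in forest:
        acc += est.tree_.predict(Xq).ravel()
    return acc / len(forest)


def _oob_importances(forest, Xm, y, groups, rng):
    """Per-variable mean OOB MSE increase under within-tree permutation."""
    group_items = list(groups.values())
    inc_sum = np.zeros(len(group_items))
    inc_cnt = 0
    base_sum = 0.0
    for est, oob in forest:
        if oob.size < 2:
            continue
        Xo = np.ascontiguousarray(Xm[oob])
        yo = y[oob]
        tree = est.tree_
        pred = tree.predict(Xo).ravel()
        base = float(np.mean((yo - pred) ** 2))
        base_sum += base
        inc_cnt += 1
        for g, cols in enumerate(group_items):
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, cols] = Xo[perm][:, cols]
            pred_p = tree.predict(Xp).ravel()
            inc_sum[g] += float(np.mean((yo - pred_p) ** 2)) - base
    if inc_cnt == 0:
        raise RuntimeError("no tree had >= 2 OOB cases; increase n")
    mean_inc = inc_sum / inc_cnt
    baseline = base_sum / inc_cnt
    return mean_inc, baseline


def _importance_core(Xm, y, groups, n_trees, seed, max_features):
    ss = np.random.SeedSequence(seed)
    s_fit, s_perm = ss.generate_state(2)
    forest = _grow_forest(Xm, y, n_trees, max_features, s_fit)
    return _oob_importances(
        forest, Xm, y, groups, np.random.default_rng(int(s_perm))
    )


def rf_importance(
    X,
    y,
    n_trees: int = 5000,
    seed: int = 0,
    max_features=1.0 / 3.0,
    mode: str = "percent",
) -> pd.Series:
    """%IncMSE permutation importance per predictor.

    ``mode="percent"`` (default) reports the mean OOB MSE increase as a
    percentage of the baseline OOB MSE; ``mode="raw"`` reports the raw
    MSE difference.  Categorical predictors are one-hot encoded
    internally and permuted jointly, so importance is reported per
    original variable.
    """
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("response is constant")
    Xm, names, groups = _encode(X)
    if Xm.shape[0] < 20:
        raise ValueError("need at least 20 observations")
    mean_inc, baseline = _importance_core(Xm, y, groups, n_trees, seed, max_features)
    if mode == "percent":
        vals = 100.0 * mean_inc / baseline
    elif mode == "raw":
        vals = mean_inc
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(vals, index=names, name="importance")


def cross_validated_r2(
    X, y, folds: int = 5, seed: int = 0, n_trees: int = 500,
    max_features=1.0 / 3.0,
) -> float:
    """Pooled out-of-fold R² from per-fold forests (may be negative)."""
    y = np.asarray(y, dtype=float)
    Xm, _, _ = _encode(X)
    n = len(y)
    if n < folds:
        raise ValueError("n must be >= folds")
    ss = np.random.SeedSequence(seed)
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(ss.generate_state(1)[0]) % MAX_SEED)
    pred = np.empty(n)
    for sub, (tr, te) in zip(ss.spawn(folds), kf.split(Xm)):
        forest = _grow_forest(Xm[tr], y[tr], n_trees, max_features,
                              sub.generate_state(1)[0])
        pred[te] = _forest_predict(forest, Xm[te])
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst


@dataclass
class ImportanceResult:
    """Observed importances with permutation significance."""

    importance: pd.Series
    p_values: pd.Series
    model_cv_r2: float | None
    model_p: float | None
    n_trees: int
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"importance_pct_inc_mse": self.importance, "p_value": self.p_values}
        ).sort_values("importance_pct_inc_mse", ascending=False)

    def to_dict(self) -> dict:
        return {
            "importance_pct_inc_mse": self.importance.to_dict(),
            "p_values": self.p_values.to_dict(),
            "model_cv_r2": self.model_cv_r2,
            "model_p": self.model_p,
            "n_trees": self.n_trees,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def permutation_significance(
    X,
    y,
    n_permutations: int = 5000,
    n_trees: int = 5000,
    seed: int = 0,
    max_features=1.0 / 3.0,
    compute_model_p: bool = True,
    cv_folds: int = 5,
    cv_trees: int | None = None,
) -> ImportanceResult:
    """Permutation-null significance for importances and the model.

    Null distributions come from re-fitting the forest on data whose
    response has been permuted; p = (1 + #{null >= observed}) /
    (1 + n_permutations), so p-values are floored at 1/(B+1).  The model
    statistic is the cross-validated R².
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    y = np.asarray(y, dtype=float)
    Xm, names, groups = _encode(X)
    ss = np.random.SeedSequence(seed)
    s_obs, s_null = ss.spawn(2)
    cv_trees = n_trees if cv_trees is None else cv_trees

    def importances(yv, sub):
        inc, base = _importance_core(
            Xm, yv, groups, n_trees, int(sub.generate_state(1)[0]), max_features
        )
        return 100.0 * inc / base

    obs = importances(y, s_obs)
    model_r2 = model_p = None
    if compute_model_p:
        model_r2 = cross_validated_r2(
            X, y, folds=cv_folds, seed=int(s_obs.generate_state(1)[0]) % MAX_SEED,
            n_trees=cv_trees, max_features=max_features,
        )

    ge = np.zeros(len(names))
    ge_model = 0
    rng_perm = np.random.default_rng(s_null)
    null_seeds = s_null.spawn(n_permutations)
    for sub in null_seeds:
        yp = rng_perm.permutation(y)
        null_imp = importances(yp, sub)
        ge += null_imp >= obs
        if compute_model_p:
            null_r2 = cross_validated_r2(
                X, yp, folds=cv_folds,
                seed=int(sub.generate_state(1)[0]) % MAX_SEED,
                n_trees=cv_trees, max_features=max_features,
            )
            ge_model += null_r2 >= model_r2
    pvals = (1.0 + ge) / (1.0 + n_permutations)
    if compute_model_p:
        model_p = (1.0 + ge_model) / (1.0 + n_permutations)
    return ImportanceResult(
        importance=pd.Series(obs, index=names, name="importance"),
        p_values=pd.Series(pvals, index=names, name="p_value"),
        model_cv_r2=model_r2,
        model_p=model_p,
        n_trees=n_trees,
        n_permutations=n_permutations,
        seed=seed,
    )


def plot_importance(result: ImportanceResult, path) -> None:
    """Importance bars ordered descending, starred by permutation p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(df)), df["importance_pct_inc_mse"], color="tab:gray")
    for i, (imp, p) in enumerate(zip(df["importance_pct_inc_mse"], df["p_value"])):
        star = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        if star:
            ax.text(i, imp, star, ha="center", va="bottom")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df.index, rotation=45, ha="right")
    ax.set_ylabel("Importance (% increase of MSE)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
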