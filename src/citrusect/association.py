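"""Explainable association battery relating genotype-value features to traits.

Covers the pairwise collinearity filter, multiple linear regression on
z-scored features, shadow-feature (permuted-copy) random-forest importance
with a binomial confirm/reject decision, partial dependence, a
decision-path pairwise interaction score, repeated shared-partition
cross-validation of MLR vs RF, and apparent vs partial correlations via
the precision matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "collinearity_filter",
    "fit_mlr",
    "shadow_importance",
    "ShadowResult",
    "partial_dependence",
    "path_interactions",
    "cross_validate",
    "partial_correlations",
    "CorrelationResult",
    "default_forest",
]

RF_N_TREES = 500  # fixed forest size, logged in outputs


def default_forest(n_estimators: int = RF_N_TREES, random_state: int | None = 0,
                   **kwargs) -> RandomForestRegressor:
    """Reference forest: 500 trees, p/3 feature subsampling per split."""
    kwargs.setdefault("max_features", 1.0 / 3.0)
    return RandomForestRegressor(n_estimators=n_estimators, random_state=random_state,
                                 **kwargs)


# ---------------------------------------------------------------------------
# collinearity filter


def collinearity_filter(
    X: pd.DataFrame,
    threshold: float = 0.95,
    policy: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedily drop one member of every feature pair with ``|r| >= threshold``.

    ``policy='deterministic'`` drops the member with the larger mean absolute
    correlation to all other features; ``policy='random'`` picks the dropped
    member at random (seeded via ``rng``).  Returns (retained names, list of
    (dropped, kept, r) decisions).
    """
    if policy not in ("deterministic", "random"):
        raise ValueError(f"unknown policy {policy!r}")
    if len(X) < 2:
        raise ValueError("need >= 2 samples to compute correlations")
    rng = np.random.default_rng(rng)
    X = X.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant columns treated as uncorrelated: {const}", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = X.corr().to_numpy()
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 0.0)
    cols = list(X.columns)
    active = set(range(len(cols)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        best = None
        for i in sorted(active):
            for jj in sorted(active):
                if jj <= i:
                    continue
                r = abs(corr[i, jj])
                if r >= threshold and (best is None or r > best[0]):
                    best = (r, i, jj)
        if best is None:
            break
        r, i, jj = best
        if policy == "random":
            drop = i if rng.random() < 0.5 else jj
        else:
            others_i = [abs(corr[i, k]) for k in active if k not in (i, jj)]
            others_j = [abs(corr[jj, k]) for k in active if k not in (i, jj)]
            mi = np.mean(others_i) if others_i else 0.0
            mj = np.mean(others_j) if others_j else 0.0
            drop = i if mi >= mj else jj
        keep = jj if drop == i else i
        dropped.append((cols[drop], cols[keep], float(np.sign(corr[i, jj]) * r or r)))
        active.remove(drop)
    retained = [cols[i] for i in sorted(active)]
    return retained, dropped


# ---------------------------------------------------------------------------
# multiple linear regression


def fit_mlr(X: pd.DataFrame, y: np.ndarray | pd.Series,
            zscore: bool = True) -> pd.DataFrame:
    """OLS of the trait on (z-scored) features with per-feature t-tests.

    z-scoring makes coefficients comparable across features; the raw-scale
    coefficient is reported alongside.  Raises on rank deficiency, naming
    the dependent columns.
    """
    import statsmodels.api as sm

    X = X.astype(float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p (n={n}, p={p})")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    if rank < p + 1:
        bad = []
        base = X.to_numpy()
        for j, c in enumerate(X.columns):
            others = np.delete(base, j, axis=1)
            resid = base[:, j] - others @ np.linalg.lstsq(others, base[:, j], rcond=None)[0]
            if np.std(resid) < 1e-10 * max(np.std(base[:, j]), 1e-30):
                bad.append(c)
        raise ValueError(f"rank-deficient design; linearly dependent columns: {bad}")

    sd = X.std(ddof=1).replace(0.0, 1.0)
    Xz = (X - X.mean()) / sd if zscore else X
    model = sm.OLS(y, sm.add_constant(Xz.to_numpy())).fit()
    out = pd.DataFrame(
        {
            "coefficient": model.params[1:],
            "stderr": model.bse[1:],
            "pvalue": model.pvalues[1:],
        },
        index=X.columns,
    )
    out["coefficient_raw"] = out["coefficient"] / sd.to_numpy() if zscore \
        else out["coefficient"]
    return out


# ---------------------------------------------------------------------------
# shadow-feature importance


@dataclass
class ShadowResult:
    decision: pd.Series                  # confirmed / rejected / tentative
    importance_history: pd.DataFrame     # iterations x features, importances
    hits: pd.Series
    iterations: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decision.index[self.decision == "confirmed"])

    @property
    def rejected(self) -> list[str]:
        return list(self.decision.index[self.decision == "rejected"])


def _bootstrap_oob(forest: RandomForestRegressor, n: int) -> list[np.ndarray]:
    """Out-of-bag row indices per tree, replaying sklearn's bootstrap draw."""
    oob = []
    for est in forest.estimators_:
        sampled = np.random.RandomState(est.random_state).randint(0, n, n)
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        oob.append(np.nonzero(mask)[0])
    return oob


def oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean out-of-bag MSE increase per feature when that feature is permuted."""
    n, p = X.shape
    imp = np.zeros(p)
    counts = np.zeros(p)
    for est, oob in zip(forest.estimators_, _bootstrap_oob(forest, n)):
        if oob.size < 2:
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean((yo - est.predict(Xo)) ** 2)
        used = np.unique(est.tree_.feature)
        for j in range(p):
            if j not in used:
                counts[j] += 1  # permuting an unused feature changes nothing
                continue
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            imp[j] += np.mean((yo - est.predict(Xp)) ** 2) - base
            counts[j] += 1
    return imp / np.maximum(counts, 1)


def shadow_importance(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    rng: np.random.Generator | None = None,
    max_iterations: int = 20,
    alpha: float = 0.05,
    n_estimators: int = 100,
) -> ShadowResult:
    """Confirm/reject features by comparison with permuted shadow copies.

    Each iteration appends a permuted copy of every feature, fits a random
    forest, and scores a "hit" for any real feature whose out-of-bag
    permutation importance exceeds the maximum shadow importance.  Features
    whose hit counts are significantly above/below chance (two-sided
    binomial test at ``alpha``) are confirmed/rejected; the rest stay
    tentative after ``max_iterations``.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    if len(X) < 20:
        raise ValueError("need n >= 20 for stable shadow comparisons")
    if np.std(y) == 0:
        warnings.warn("constant response: all features rejected", stacklevel=2)
        dec = pd.Series("rejected", index=X.columns)
        return ShadowResult(dec, pd.DataFrame(columns=X.columns),
                            pd.Series(0, index=X.columns), 0)

    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    hits = pd.Series(0, index=cols, dtype=int)
    trials = pd.Series(0, index=cols, dtype=int)
    decision = pd.Series("tentative", index=cols, dtype=object)
    history = []

    for it in range(max_iterations):
        undecided = [c for c in cols if decision[c] == "tentative"]
        if not undecided:
            break
        shadows = Xv.copy()
        for j in range(p):
            shadows[:, j] = shadows[rng.permutation(n), j]
        Xaug = np.hstack([Xv, shadows])
        forest = default_forest(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(Xaug, y)
        imp = oob_permutation_importance(forest, Xaug, y, rng)
        real, shadow = imp[:p], imp[p:]
        thr = shadow.max()
        history.append(pd.Series(real, index=cols, name=it))
        for j, c in enumerate(cols):
            if decision[c] != "tentative":
                continue
            trials[c] += 1
            if real[j] > thr:
                hits[c] += 1
            k, m = hits[c], trials[c]
            p_hi = stats.binomtest(k, m, 0.5, alternative="greater").pvalue
            p_lo = stats.binomtest(k, m, 0.5, alternative="less").pvalue
            if p_hi < alpha / 2:
                decision[c] = "confirmed"
            elif p_lo < alpha / 2:
                decision[c] = "rejected"

    return ShadowResult(
        decision=decision,
        importance_history=pd.DataFrame(history),
        hits=hits,
        iterations=len(history),
    )


# ---------------------------------------------------------------------------
# partial dependence & path interactions


def partial_dependence(
    forest, X: pd.DataFrame, feature: str, grid_size: int = 20
) -> pd.DataFrame:
    """Mean model prediction as the named feature sweeps a quantile grid."""
    if feature not in X.columns:
        raise KeyError(f"unknown feature {feature!r}")
    col = list(X.columns).index(feature)
    Xv = X.to_numpy(dtype=float)
    grid = np.quantile(Xv[:, col], np.linspace(0.0, 1.0, grid_size))
    means = []
    work = Xv.copy()
    for v in grid:
        work[:, col] = v
        means.append(float(np.mean(forest.predict(work))))
    return pd.DataFrame({"grid": grid, "prediction": means})


def path_interactions(forest, min_leaf_fraction: float = 0.0) -> pd.DataFrame:
    """Pairwise feature co-occurrence on root-to-leaf decision paths.

    score(i, j) = fraction of paths ending in leaves that hold at least
    ``min_leaf_fraction`` of the training samples on which both features
    split, averaged over trees.  A coarse surrogate for iterative-forest
    interaction discovery.
    """
    p = forest.n_features_in_
    score = np.zeros((p, p))
    for est in forest.estimators_:
        tree = est.tree_
        n_root = tree.n_node_samples[0]
        pair_counts = np.zeros((p, p))
        n_paths = 0

        def walk(node: int, feats: frozenset) -> None:
            nonlocal n_paths
            if tree.children_left[node] == -1:
                if tree.n_node_samples[node] >= min_leaf_fraction * n_root:
                    n_paths += 1
                    fl = sorted(feats)
                    for ai in range(len(fl)):
                        for bi in range(ai + 1, len(fl)):
                            pair_counts[fl[ai], fl[bi]] += 1
                return
            f = tree.feature[node]
            nxt = feats | {int(f)}
            walk(int(tree.children_left[node]), nxt)
            walk(int(tree.children_right[node]), nxt)

        walk(0, frozenset())
        if n_paths:
            score += pair_counts / n_paths
    score /= len(forest.estimators_)
    score = score + score.T
    names = getattr(forest, "feature_names_in_", np.arange(p).astype(str))
    return pd.DataFrame(score, index=names, columns=names)


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    folds: int = 10,
    repeats: int = 5,
    rng: np.random.Generator | None = None,
    models: dict | None = None,
) -> dict:
    """Repeated k-fold CV with fold partitions shared across models.

    Returns per-repeat out-of-fold Pearson r and RMSE for each model, their
    means and s.d.s, and paired t-tests across repeats comparing the two
    models (mirrors the MLR-vs-RF comparison design).
    """
    rng = np.random.default_rng(rng)
    X = X.astype(float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    if models is None:
        models = {
            "MLR": LinearRegression(),
            "RF": default_forest(random_state=int(rng.integers(0, 2**31 - 1))),
        }
    per_repeat: dict[str, dict[str, list[float]]] = {
        m: {"r": [], "rmse": []} for m in models
    }
    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31 - 1)))
        splits = list(kf.split(X))
        for name, proto in models.items():
            pred = np.empty(n)
            for tr, te in splits:
                if len(te) < 2:
                    raise ValueError("fold with < 2 samples")
                import sklearn.base

                model = sklearn.base.clone(proto)
                model.fit(X.iloc[tr].to_numpy(), y[tr])
                pred[te] = model.predict(X.iloc[te].to_numpy())
            per_repeat[name]["r"].append(float(np.corrcoef(pred, y)[0, 1]))
            per_repeat[name]["rmse"].append(float(np.sqrt(np.mean((pred - y) ** 2))))

    table = pd.DataFrame(
        {
            (m, k): pd.Series(v[k])
            for m, v in per_repeat.items()
            for k in ("r", "rmse")
        }
    )
    summary = table.agg(["mean", "std"])
    comparison = {}
    names = list(models)
    if len(names) == 2 and repeats > 1:
        a, b = names
        for k in ("r", "rmse"):
            t, pv = stats.ttest_rel(table[(a, k)], table[(b, k)])
            comparison[k] = {"t": float(t), "pvalue": float(pv)}
    return {"per_repeat": table, "summary": summary, "comparison": comparison}


# ---------------------------------------------------------------------------
# apparent & partial correlations


@dataclass
class CorrelationResult:
    apparent: pd.DataFrame
    apparent_pvalues: pd.DataFrame
    partial: pd.DataFrame
    partial_pvalues: pd.DataFrame
    n: int = field(default=0)


def partial_correlations(data: pd.DataFrame) -> CorrelationResult:
    """Apparent (marginal) and partial correlations among all columns.

    The partial correlation between i and j controls for every other
    column, computed from the inverse correlation matrix:
    ``rho_ij = -O_ij / sqrt(O_ii * O_jj)``.  Significance uses the t
    statistic on ``n - 2 - k`` degrees of freedom (k = number of controls).
    """
    data = data.astype(float)
    n, p = data.shape
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    cols = list(data.columns)
    R = data.corr().to_numpy()
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            "correlation matrix is singular; remove collinear features first "
            "(see collinearity_filter)"
        )
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)

    def pvals(mat: np.ndarray, df: int) -> np.ndarray:
        r = np.clip(mat, -0.999999999, 0.999999999)
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
        pv = 2 * stats.t.sf(np.abs(t), df)
        np.fill_diagonal(pv, 0.0)
        return pv

    k = p - 2
    app_p = pvals(R, n - 2)
    par_p = pvals(partial, n - 2 - k)
    as_df = lambda m: pd.DataFrame(m, index=cols, columns=cols)
    return CorrelationResult(
        apparent=as_df(R),
        apparent_pvalues=as_df(app_p),
        partial=as_df(partial),
        partial_pvalues=as_df(par_p),
        n=n,
    )
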