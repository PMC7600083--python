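"""Statistical association layer.

z-score PCA, covariate residualization, alpha-diversity regressions,
PERMANOVA, symmetric Procrustes with a permutation test, and a
regression random forest that selects OTU communities associated with
each diet variable (importance = out-of-bag MSE increase, direction =
Spearman correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.tree import DecisionTreeRegressor

COVARIATE_COLUMNS = ["city", "sex", "age_group", "bmi_class", "ses"]


# ---------------------------------------------------------------------------
# PCA on z-scored variables

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    variance_explained: np.ndarray  # fractions, all components
    dropped: list[str] = field(default_factory=list)


def zscore_pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of column-standardized data via SVD.

    Constant columns are dropped with a warning; loading signs are fixed
    so the largest-magnitude entry of each column is positive.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    X = matrix.astype(float)
    sd = X.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    Z = (X - X.mean()) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # sign convention: largest |loading| per component positive
    for k in range(Vt.shape[0]):
        if Vt[k, np.argmax(np.abs(Vt[k]))] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2 / np.sum(S**2)
    k = n_components or len(S)
    comp_names = [f"PC{i + 1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(
            (U * S)[:, :k], index=matrix.index, columns=comp_names[:k]
        ),
        loadings=pd.DataFrame(Vt.T[:, :k], index=X.columns, columns=comp_names[:k]),
        variance_explained=var,
        dropped=constant,
    )


# ---------------------------------------------------------------------------
# covariate adjustment

def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
    dummies = pd.get_dummies(
        covariates[cols].astype(str), drop_first=True, dtype=float
    )
    X = np.column_stack([np.ones(len(covariates)), dummies.to_numpy()])
    return X


def residualize(y: np.ndarray | pd.Series, covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of y regressed on dummy-coded covariates (mean ~0).

    Rank-deficient designs are handled by least squares on the pseudo-
    inverse (aliased columns contribute nothing).
    """
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(covariates):
        raise ValueError("y and covariates must align")
    X = _design_matrix(covariates)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ beta


def alpha_regression(
    alpha: pd.Series | np.ndarray,
    diet_var: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
) -> dict[str, float]:
    """Linear model alpha ~ covariates + diet variable.

    Reports the diet term's coefficient, its 1-df partial F and p-value.
    """
    y = np.asarray(alpha, dtype=float)
    d = np.asarray(diet_var, dtype=float)
    if d.std() == 0:
        raise ValueError("diet variable has zero variance")
    X0 = _design_matrix(covariates)
    # aliasing check: diet var must not be in the covariate span
    resid_d = d - X0 @ np.linalg.lstsq(X0, d, rcond=None)[0]
    if np.sqrt(np.mean(resid_d**2)) < 1e-10 * max(1.0, np.std(d)):
        raise ValueError("diet variable is aliased with the covariates")
    X1 = np.column_stack([X0, d])
    rank0 = np.linalg.matrix_rank(X0)
    rank1 = np.linalg.matrix_rank(X1)
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta1) ** 2))
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))
    df_resid = len(y) - rank1
    f = (rss0 - rss1) / (rss1 / df_resid)
    p = float(stats.f.sf(f, rank1 - rank0, df_resid))
    return {
        "coef": float(beta1[-1]),
        "F": float(f),
        "p": p,
        "df_num": rank1 - rank0,
        "df_den": df_resid,
    }


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_perm: int


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    f = (ss_between / df_between) / (ss_within / df_within)
    return f, ss_between / ss_total


def permanova(
    dist: pd.DataFrame,
    factor: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Pseudo-F partitions squared distances between and within groups;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    codes, uniques = pd.factorize(np.asarray(factor))
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("factor needs >= 2 levels")
    d2 = D**2
    f_obs, r2 = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        f_perm, _ = _permanova_f(d2, codes[perm], n_groups)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(r2=r2, pseudo_f=f_obs, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# principal coordinates (for the microbiota side of Procrustes)

def pcoa(dist: pd.DataFrame, n_axes: int = 3) -> pd.DataFrame:
    """Classical MDS of a distance matrix; first ``n_axes`` real axes."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    vals, vecs = vals[pos], vecs[:, pos]
    k = min(n_axes, len(vals))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return pd.DataFrame(
        coords, index=dist.index, columns=[f"Axis{i + 1}" for i in range(k)]
    )


# ---------------------------------------------------------------------------
# symmetric Procrustes with permutation test

@dataclass
class ProcrustesResult:
    correlation: float
    m2: float
    p_value: float
    n_perm: int


def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> float:
    # inputs already centered and unit-scaled
    s = np.linalg.svd(X.T @ Y, compute_uv=False)
    return 1.0 - float(s.sum()) ** 2


def _center_scale(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    norm = np.sqrt(np.sum(M**2))
    if norm == 0:
        raise ValueError("configuration has zero variance")
    return M / norm


def procrustes_test(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes fit of two configurations + permutation test.

    Both matrices are centered and scaled to unit sum of squares; the
    optimal rotation comes from the SVD of X'Y. m2 = 1 - (sum singular
    values)^2 and correlation = sqrt(1 - m2). The null distribution
    permutes rows of one configuration; p uses the +1 convention.
    """
    Xv = np.asarray(X, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    Xc = _center_scale(Xv)
    Yc = _center_scale(Yv)
    m2 = _procrustes_m2(Xc, Yc)
    corr = float(np.sqrt(max(0.0, 1.0 - m2)))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(Xc.shape[0])
        # permuted rows must be re-centered/scaled? centering is
        # permutation-invariant, so reuse the centered matrix directly
        if _procrustes_m2(Xc[perm], Yc) <= m2:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return ProcrustesResult(correlation=corr, m2=m2, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# random-forest OTU-community selection

@dataclass
class RFAssociation:
    diet_variable: str
    selected_otus: list[str]
    importance: pd.Series  # MSE increase, non-increasing, selected OTUs
    explained_variance: float  # OOB R^2 of the selected model
    spearman_rho: pd.Series  # direction, selected OTUs
    full_importance: pd.Series = None  # all OTUs, from the full model
    rfe_path: list[tuple[int, float]] = field(default_factory=list)


class _Forest:
    """Bagged regression trees with an explicit OOB bookkeeping.

    Each tree trains on a random two-thirds of the samples drawn without
    replacement; the held-out third is its OOB set, used for the
    explained-variance estimate and permutation importance.
    """

    def __init__(self, n_trees: int, max_features: float, seed: int):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        n_train = max(2, (2 * n) // 3)
        max_feat = max(1, int(round(self.max_features * X.shape[1])))
        for t in range(self.n_trees):
            train = rng.choice(n, size=n_train, replace=False)
            mask = np.ones(n, dtype=bool)
            mask[train] = False
            tree = DecisionTreeRegressor(
                max_features=max_feat,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[train], y[train])
            self.trees.append(tree)
            self.oob_masks.append(mask)
        return self

    def _oob_predict(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        for tree, mask in zip(self.trees, self.oob_masks):
            pred_sum[mask] += tree.predict(X[mask])
            pred_cnt[mask] += 1
        covered = pred_cnt > 0
        out = np.full(n, np.nan)
        out[covered] = pred_sum[covered] / pred_cnt[covered]
        return out

    def oob_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self._oob_predict(X)
        ok = ~np.isnan(pred)
        mse = float(np.mean((y[ok] - pred[ok]) ** 2))
        return 1.0 - mse / float(np.var(y[ok]))

    def oob_importance(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        """Mean OOB MSE increase when one feature is permuted."""
        rng = np.random.default_rng(seed)
        pred = self._oob_predict(X)
        ok = ~np.isnan(pred)
        base_mse = float(np.mean((y[ok] - pred[ok]) ** 2))
        imp = np.zeros(X.shape[1])
        for j in range(X.shape[1]):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pj = self._oob_predict(Xp)
            okj = ~np.isnan(pj)
            imp[j] = float(np.mean((y[okj] - pj[okj]) ** 2)) - base_mse
        return imp


def rf_diet_association(
    otu_rel: pd.DataFrame,
    diet_adjusted: pd.Series | np.ndarray,
    n_trees: int = 1000,
    seed: int = 0,
    max_features: float = 1 / 3,
    min_subset: int = 2,
    diet_variable: str = "diet",
    rfe: bool = True,
) -> RFAssociation:
    """Select the OTU community most predictive of one diet variable.

    Fits a bagged regression forest (2/3 train, 1/3 OOB per tree),
    measures importance as OOB MSE increase under feature permutation,
    then runs recursive feature elimination over a halving schedule and
    keeps the OTU subset that maximizes OOB explained variance. The
    direction of each selected OTU is its Spearman correlation with the
    (already covariate-adjusted) diet variable.
    """
    y = np.asarray(diet_adjusted, dtype=float)
    if y.std() == 0:
        raise ValueError("diet variable is constant")
    if otu_rel.shape[0] != len(y):
        raise ValueError("otu_rel rows must align with the diet variable")
    X_full = otu_rel.to_numpy(dtype=float)
    otus = list(otu_rel.columns)

    current = list(range(len(otus)))
    best: tuple[float, list[int], np.ndarray] | None = None
    full_importance: np.ndarray | None = None
    path: list[tuple[int, float]] = []
    level = 0
    while True:
        X = X_full[:, current]
        forest = _Forest(n_trees, max_features, seed + level).fit(X, y)
        r2 = forest.oob_r2(X, y)
        imp = forest.oob_importance(X, y, seed + 10_000 + level)
        if full_importance is None:
            full_importance = imp
        path.append((len(current), r2))
        order = np.argsort(imp)[::-1]
        if best is None or r2 > best[0]:
            best = (r2, [current[k] for k in order], imp[order])
        if not rfe or len(current) <= min_subset:
            break
        keep = max(min_subset, len(current) // 2)
        current = [current[k] for k in order[:keep]]
        level += 1

    r2_best, sel, sel_imp_values = best
    sel_names = [otus[k] for k in sel]
    rho = pd.Series(
        {otus[k]: stats.spearmanr(X_full[:, k], y).statistic for k in sel},
        name="spearman_rho",
    )
    sel_imp = pd.Series(sel_imp_values, index=sel_names, name="importance")
    return RFAssociation(
        diet_variable=diet_variable,
        selected_otus=sel_names,
        importance=sel_imp,
        explained_variance=r2_best,
        spearman_rho=rho.loc[sel_names],
        full_importance=pd.Series(full_importance, index=otus, name="mse_increase"),
        rfe_path=path,
    )


def association_heatmap_table(
    rf_results: list[RFAssociation],
    otu_rel: pd.DataFrame,
    diet_values: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long table (otu, diet_variable, rho, selected, class) over the
    union of selected OTUs, with Ward-linkage row/column orders.
    """
    union: list[str] = []
    selected: dict[str, set] = {}
    for res in rf_results:
        for otu in res.selected_otus:
            if otu not in selected:
                selected[otu] = set()
                union.append(otu)
            selected[otu].add(res.diet_variable)
    if not union:
        return pd.DataFrame(
            columns=["otu_id", "diet_variable", "rho", "selected", "class", "otu_order"]
        )
    variables = [r.diet_variable for r in rf_results]
    rho = pd.DataFrame(index=union, columns=variables, dtype=float)
    for var in variables:
        y = diet_values[var].to_numpy(dtype=float)
        for otu in union:
            rho.loc[otu, var] = stats.spearmanr(
                otu_rel[otu].to_numpy(dtype=float), y
            ).statistic
    if len(union) > 2:
        order = leaves_list(linkage(rho.fillna(0.0).to_numpy(), method="ward"))
    else:
        order = np.arange(len(union))
    rank = {union[k]: i for i, k in enumerate(order)}
    cls = (
        taxonomy.set_index("otu_id")["class"] if taxonomy is not None else None
    )
    rows = []
    for otu in union:
        for var in variables:
            rows.append(
                {
                    "otu_id": otu,
                    "diet_variable": var,
                    "rho": rho.loc[otu, var],
                    "selected": var in selected[otu],
                    "class": cls.get(otu, "unclassified") if cls is not None else "",
                    "otu_order": rank[otu],
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["otu_order", "diet_variable"], ignore_index=True
    )
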