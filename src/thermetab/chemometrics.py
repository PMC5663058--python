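"""Chemometrics: imputation, autoscaling, orthogonal-scores PLS, VIP, PCA.

The modelling core regresses a single physiological response (canopy or
stomatal conductance) on a plants x metabolites abundance matrix using
orthogonal-scores (NIPALS) partial least squares. With one response the
NIPALS weight step is exact, w_a = X_a' y_a / ||X_a' y_a||; scores
t_a = X_a w_a are mutually orthogonal by deflation, and the regression
coefficients on the autoscaled predictor scale are B = W (P'W)^-1 q.

Predictive power is assessed by cross-validated RMSEP with a bias-corrected
("adjusted") variant, and per-predictor influence by variable importance in
projection,

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a't_a,

whose squares average to one; predictors with VIP above the mean are the
selected set.

Predictors are autoscaled (column mean 0, SD 1); the response is centered
but not scaled, following the single-response chemometrics convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer

__all__ = [
    "MetaboliteMatrix",
    "PLSModel",
    "CVResult",
    "VIPResult",
    "impute_missing",
    "autoscale",
    "pls_fit",
    "cross_validate",
    "select_components",
    "vip_scores",
    "pca_overview",
]


@dataclass
class MetaboliteMatrix:
    """Plants x metabolites relative abundances with treatment labels.

    ``values`` is a DataFrame (rows = plants, columns = metabolites; NaN for
    missing cells); ``treatments`` a Series aligned on the plant index.
    """

    values: pd.DataFrame
    treatments: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.treatments = pd.Series(self.treatments)
        if not self.values.index.equals(self.treatments.index):
            self.treatments = self.treatments.reindex(self.values.index)
            if self.treatments.isna().any():
                raise ValueError("treatments do not cover all plants")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate metabolite names: {dup}")
        counts = self.treatments.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValueError(f"treatments with < 2 plants: {small}")

    @property
    def plant_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_names(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_csv(self, path) -> None:
        """Write as CSV: plant_id, treatment, then one column per metabolite."""
        out = self.values.copy()
        out.insert(0, "treatment", self.treatments)
        out.index.name = "plant_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "MetaboliteMatrix":
        df = pd.read_csv(path, index_col="plant_id")
        if "treatment" not in df.columns:
            raise ValueError("metabolite CSV must have a 'treatment' column")
        return cls(values=df.drop(columns="treatment"), treatments=df["treatment"])


def impute_missing(
    matrix: MetaboliteMatrix, method: str = "iterative", seed: int = 0
) -> MetaboliteMatrix:
    """Fill missing abundance cells; observed cells are never modified.

    Methods: ``mean`` (column mean of observed values), ``knn`` (5-nearest
    samples), ``iterative`` (default; chained-prediction imputer with
    tree-ensemble regressors, seeded and deterministic). A metabolite with no
    observed value at all cannot be imputed and raises, naming it.
    """
    X = matrix.values
    fully_missing = X.columns[X.isna().all(axis=0)].tolist()
    if fully_missing:
        raise ValueError(f"metabolites with no observed values: {fully_missing}")
    if not X.isna().to_numpy().any():
        return MetaboliteMatrix(values=X.copy(), treatments=matrix.treatments.copy())

    if method == "mean":
        filled = X.fillna(X.mean(axis=0))
    elif method == "knn":
        imp = KNNImputer(n_neighbors=min(5, len(X) - 1))
        filled = pd.DataFrame(imp.fit_transform(X), index=X.index, columns=X.columns)
    elif method == "iterative":
        est = ExtraTreesRegressor(n_estimators=30, random_state=seed)
        imp = IterativeImputer(
            estimator=est, max_iter=5, random_state=seed, keep_empty_features=False
        )
        with warnings.catch_warnings():
            # a fixed small iteration cap is deliberate at these matrix sizes
            warnings.filterwarnings("ignore", message=".*Early stopping criterion.*")
            filled = pd.DataFrame(
                imp.fit_transform(X), index=X.index, columns=X.columns
            )
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    # guarantee observed cells untouched (imputer contract, enforced here)
    filled = filled.where(X.isna(), X)
    return MetaboliteMatrix(values=filled, treatments=matrix.treatments.copy())


def autoscale(X) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Center each column to mean 0 and scale to SD 1 (ddof=1).

    Zero-variance columns carry no information on the autoscaled scale and
    are dropped with a warning. Returns ``(X_scaled, centers, scales)``;
    ``X_scaled * scales + centers`` restores the retained columns.
    """
    X = pd.DataFrame(X)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    dead = scales[scales == 0.0].index.tolist()
    if dead:
        warnings.warn(
            f"dropping zero-variance columns: {dead}", UserWarning, stacklevel=2
        )
        X = X.drop(columns=dead)
        centers = centers.drop(dead)
        scales = scales.drop(dead)
    return (X - centers) / scales, centers, scales


@dataclass
class PLSModel:
    """Fitted single-response orthogonal-scores PLS model.

    Weights ``W`` (p x A, unit columns), x-loadings ``P``, y-loadings ``q``,
    scores ``T`` (n x A, orthogonal columns), coefficients ``b`` on the
    autoscaled-X / centered-y scale, plus the centering/scaling vectors
    needed to predict from raw predictors.
    """

    n_comp: int
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    x_center: pd.Series
    x_scale: pd.Series
    y_center: float
    feature_names: pd.Index
    scale_x: bool = True

    def coefficients(self, n_comp: int | None = None) -> pd.Series:
        """Regression coefficients using the first ``n_comp`` components."""
        a = self.n_comp if n_comp is None else n_comp
        b = _coef_from_decomposition(self.W[:, :a], self.P[:, :a], self.q[:a])
        return pd.Series(b, index=self.feature_names)

    def predict(self, X, n_comp: int | None = None) -> np.ndarray:
        """Predict the response for raw (unscaled) predictors ``X``."""
        X = pd.DataFrame(X)[self.feature_names]
        Xs = (X - self.x_center) / self.x_scale if self.scale_x else X - self.x_center
        b = self.coefficients(n_comp).to_numpy()
        return self.y_center + Xs.to_numpy() @ b


def _coef_from_decomposition(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    R = W @ np.linalg.inv(P.T @ W)  # rotation mapping X directly to scores
    return R @ q


def _nipals_single_y(
    Xs: np.ndarray, yc: np.ndarray, n_comp: int, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Orthogonal-scores NIPALS for a single centered response."""
    n, p = Xs.shape
    W = np.zeros((p, n_comp))
    Pl = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    T = np.zeros((n, n_comp))
    X_work, y_work = Xs.copy(), yc.copy()
    norm0 = np.linalg.norm(Xs.T @ yc)
    used = 0
    for a in range(n_comp):
        w = X_work.T @ y_work
        nw = np.linalg.norm(w)
        if nw <= tol * max(norm0, 1.0):
            warnings.warn(
                f"rank exhausted after {used} components (requested {n_comp})",
                UserWarning,
                stacklevel=3,
            )
            break
        w /= nw
        # sign convention: largest-magnitude weight element positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = X_work @ w
        tt = t @ t
        if tt <= tol:
            break
        p_a = X_work.T @ t / tt
        q_a = (y_work @ t) / tt
        X_work -= np.outer(t, p_a)
        y_work = y_work - q_a * t
        W[:, a], Pl[:, a], q[a], T[:, a] = w, p_a, q_a, t
        used += 1
    return W[:, :used], Pl[:, :used], q[:used], T[:, :used], used


def pls_fit(X, y, n_comp: int, scale: bool = True) -> PLSModel:
    """Fit a single-response orthogonal-scores PLS model.

    ``X`` is the raw plants x metabolites matrix (autoscaled internally when
    ``scale`` is True, the default); ``y`` the response vector (centered
    internally, never scaled). ``n_comp`` must not exceed
    ``min(n_samples - 1, n_features)``; rank exhaustion during deflation
    reduces the component count with a warning.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y have different numbers of samples")
    if not (1 <= n_comp <= min(n - 1, p)):
        raise ValueError(
            f"n_comp={n_comp} outside [1, min(n-1={n - 1}, p={p})]"
        )
    if scale:
        Xs_df, centers, scales = autoscale(X)
    else:
        centers = X.mean(axis=0)
        scales = pd.Series(1.0, index=X.columns)
        Xs_df = X - centers
    y_center = float(np.mean(y))
    W, Pl, q, T, used = _nipals_single_y(
        Xs_df.to_numpy(dtype=float), y - y_center, n_comp
    )
    return PLSModel(
        n_comp=used,
        W=W,
        P=Pl,
        q=q,
        T=T,
        b=_coef_from_decomposition(W, Pl, q),
        x_center=centers,
        x_scale=scales,
        y_center=y_center,
        feature_names=Xs_df.columns,
        scale_x=scale,
    )


@dataclass
class CVResult:
    """Cross-validation curves for component counts 0..max_comp.

    ``rmsep_cv[a]`` is the raw cross-validated RMSEP with ``a`` components
    (index 0 = intercept-only baseline); ``rmsep_adj`` the bias-corrected
    (adjusted) variant; ``r2_cv``/``r2_train`` the cross-validated and fitted
    coefficients of determination. ``n_comp`` is the selected component
    count, the argmin of the adjusted RMSEP over 1..max_comp (ties toward
    fewer components).
    """

    rmsep_cv: np.ndarray
    rmsep_adj: np.ndarray
    r2_cv: np.ndarray
    r2_train: np.ndarray
    n_comp: int = field(default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_comp": np.arange(len(self.rmsep_cv)),
                "rmsep_cv": self.rmsep_cv,
                "rmsep_adj": self.rmsep_adj,
                "r2_cv": self.r2_cv,
                "r2_train": self.r2_train,
            }
        )


def _cv_folds(n: int, scheme: str, n_folds: int, seed: int | None):
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    if scheme == "kfold":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        return [np.sort(f) for f in np.array_split(perm, n_folds)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X,
    y,
    max_comp: int,
    scheme: str = "loo",
    n_folds: int = 7,
    seed: int | None = 0,
    scale: bool = True,
) -> CVResult:
    """Cross-validate PLS over component counts 0..max_comp.

    Leave-one-out by default (natural at the small n of field campaigns);
    ``scheme="kfold"`` gives seeded k-fold. Reports the raw CV RMSEP and the
    bias-corrected (adjusted) RMSEP,

        MSEP_adj(a) = MSEP_train(a) + MSEP_cv(a) - mean_k MSEP_all(model_-k, a),

    where the last term is the average error of each fold-model over all n
    samples; the correction removes the optimism of the training error
    without the full variance of raw CV. R^2 curves are reported both
    cross-validated (1 - PRESS/TSS) and fitted.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    max_comp = int(min(max_comp, n - 2, X.shape[1]))
    if max_comp < 1:
        raise ValueError("not enough samples/features for cross-validation")

    folds = _cv_folds(n, scheme, n_folds, seed)
    n_curve = max_comp + 1
    press = np.zeros(n_curve)  # sum of squared CV prediction errors
    mse_all_sub = np.zeros(n_curve)  # fold-model error over all samples

    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X.iloc[train_mask], y[train_mask]
        fold_max = int(min(max_comp, train_mask.sum() - 1, X.shape[1]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = pls_fit(X_tr, y_tr, fold_max, scale=scale)
        for a in range(n_curve):
            aa = min(a, model.n_comp)
            pred_test = (
                np.full(len(test_idx), model.y_center)
                if a == 0
                else model.predict(X.iloc[test_idx], n_comp=aa)
            )
            press[a] += float(np.sum((y[test_idx] - pred_test) ** 2))
            pred_all = (
                np.full(n, model.y_center) if a == 0 else model.predict(X, n_comp=aa)
            )
            mse_all_sub[a] += float(np.mean((y - pred_all) ** 2)) / len(folds)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        full = pls_fit(X, y, max_comp, scale=scale)
    mse_train = np.empty(n_curve)
    mse_train[0] = float(np.mean((y - full.y_center) ** 2))
    for a in range(1, n_curve):
        aa = min(a, full.n_comp)
        mse_train[a] = float(np.mean((y - full.predict(X, n_comp=aa)) ** 2))

    msep_cv = press / n
    msep_adj = np.maximum(mse_train + msep_cv - mse_all_sub, 0.0)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    result = CVResult(
        rmsep_cv=np.sqrt(msep_cv),
        rmsep_adj=np.sqrt(msep_adj),
        r2_cv=1.0 - press / tss,
        r2_train=1.0 - mse_train * n / tss,
    )
    result.n_comp = select_components(result)
    return result


def select_components(cv: CVResult) -> int:
    """Component count minimising the adjusted RMSEP (ties toward fewer)."""
    curve = cv.rmsep_adj[1:]
    if curve.size == 0:
        raise ValueError("CV curve has no component entries")
    return int(np.argmin(curve)) + 1


@dataclass
class VIPResult:
    """Per-metabolite variable importance in projection.

    ``vip`` sums in squares to the number of predictors; ``above_mean`` marks
    the selected metabolites (VIP greater than the mean VIP); ``ranking``
    lists metabolites by decreasing VIP.
    """

    vip: pd.Series
    above_mean: pd.Series
    ranking: list[str]


def vip_scores(model: PLSModel, n_comp: int | None = None) -> VIPResult:
    """VIP scores from a fitted model's first ``n_comp`` components."""
    a = model.n_comp if n_comp is None else int(n_comp)
    if not (1 <= a <= model.n_comp):
        raise ValueError(f"n_comp={n_comp} outside [1, {model.n_comp}]")
    W = model.W[:, :a]
    ss = model.q[:a] ** 2 * np.einsum("ia,ia->a", model.T[:, :a], model.T[:, :a])
    p = W.shape[0]
    vip = np.sqrt(p * (W**2 @ ss) / ss.sum())
    vip_s = pd.Series(vip, index=model.feature_names, name="VIP")
    above = vip_s > vip_s.mean()
    ranking = vip_s.sort_values(ascending=False).index.tolist()
    return VIPResult(vip=vip_s, above_mean=above, ranking=ranking)


def pca_overview(
    X, n_comp: int = 5, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered (optionally autoscaled) PCA of the metabolite matrix.

    Returns the sample scores and the explained-variance fractions
    (non-increasing, summing to at most 1).
    """
    X = pd.DataFrame(X)
    if scale:
        Xs, _, _ = autoscale(X)
    else:
        Xs = X - X.mean(axis=0)
    n_comp = int(min(n_comp, min(Xs.shape) - 1)) or 1
    pca = _SkPCA(n_components=n_comp)
    scores = pca.fit_transform(Xs.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=X.index, columns=cols), pca.explained_variance_ratio_
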