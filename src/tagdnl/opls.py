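"""PCA, PLS-DA and OPLS-DA with the standard chemometric validation suite.

OPLS-DA separates class-predictive from class-orthogonal variation
(Trygg-Wold filtering): per orthogonal component, with w ∝ X'y,

    p   = X't / (t't)
    w_o ∝ p - (w'p / w'w) w,   t_o = X w_o,   p_o = X't_o / (t_o't_o)

the orthogonal score t_o p_o' is removed from X, and a single predictive
component is fitted on the filtered matrix. Model quality is reported as
R²X / R²Y (explained variation) and Q² (k-fold cross-validated predictive
ability, with scaling re-estimated inside every fold); validity is assessed
by the random label-permutation test and by CV-ANOVA on the cross-validated
residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve

from .preprocess import Scaler

__all__ = [
    "PcaModel",
    "pca_fit",
    "OplsModel",
    "oplsda_fit",
    "opls_predict",
    "splot",
    "PermutationReport",
    "permutation_test",
    "cv_anova",
    "predict_and_roc",
    "plsda_vip",
]


# ---------------------------------------------------------------------------
# PCA (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    scaler: Scaler


def pca_fit(X, n_components: int = 2, scaling: str = "center") -> PcaModel:
    """NIPALS principal components of the scaled matrix.

    Components beyond the matrix rank are truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(dims)={min(X.shape)}")
    scaler = Scaler(method=scaling)
    E = scaler.fit_transform(X)
    total_ss = float((E**2).sum())
    scores, loadings, evr = [], [], []
    for _ in range(n_components):
        resid = float((E**2).sum())
        if total_ss == 0 or resid / max(total_ss, 1e-300) < 1e-12:
            warnings.warn("requested components exceed matrix rank; truncating")
            break
        t = E[:, int(np.argmax(E.var(axis=0)))].copy()
        for _ in range(500):
            p = E.T @ t / (t @ t)
            p /= np.linalg.norm(p)
            t_new = E @ p
            if np.linalg.norm(t_new - t) <= 1e-12 * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                break
            t = t_new
        E = E - np.outer(t, p)
        scores.append(t)
        loadings.append(p)
        evr.append((t @ t) / total_ss)
    return PcaModel(
        np.column_stack(scores) if scores else np.empty((X.shape[0], 0)),
        np.column_stack(loadings) if loadings else np.empty((E.shape[1], 0)),
        np.asarray(evr),
        scaler,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _opls_core(Xs: np.ndarray, yc: np.ndarray, n_ortho: int) -> dict:
    """Orthogonal filtering followed by one predictive component."""
    E = Xs.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        w = E.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("X carries no covariance with y (constant y?)")
        w /= nw
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = E.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with y (constant y?)")
    w /= nw
    t = E @ w
    p = E.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    stack = lambda lst, d: np.column_stack(lst) if lst else np.empty((d, 0))
    return {
        "w": w,
        "t": t,
        "p": p,
        "q": q,
        "W_o": stack(W_o, Xs.shape[1]),
        "T_o": stack(T_o, Xs.shape[0]),
        "P_o": stack(P_o, Xs.shape[1]),
        "E": E - np.outer(t, p),
        "n_ortho": len(W_o),
    }


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (single predictive component, binary y)."""

    scaler: Scaler
    y_mean: float
    classes_: tuple
    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: float
    W_o: np.ndarray
    T_o: np.ndarray
    P_o: np.ndarray
    E: np.ndarray
    r2x: float
    r2y: float
    q2: float
    n_ortho: int
    n_folds: int
    seed: int
    cv_press: float
    cv_ssy: float
    n_samples: int
    threshold: float
    feature_names: list | None = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "n_ortho": self.n_ortho,
            "n_folds": self.n_folds,
            "classes": [str(c) for c in self.classes_],
            "n_samples": self.n_samples,
        }


def _encode_y(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {classes.size}")
    return (y == classes[1]).astype(float), (classes[0], classes[1])


def _cv_folds(y01: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold map (venetian blinds on a seeded shuffle)."""
    rng = np.random.default_rng(seed)
    fold = np.empty(y01.shape[0], dtype=int)
    for cls in (0.0, 1.0):
        idx = rng.permutation(np.where(y01 == cls)[0])
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _cv_press(X, y01, n_ortho, n_folds, scaling, seed) -> tuple[float, float]:
    fold = _cv_folds(y01, n_folds, seed)
    press = ssy = 0.0
    for f in range(n_folds):
        val = fold == f
        if not val.any():
            continue
        Xtr, ytr = X[~val], y01[~val]
        if np.unique(ytr).size < 2:
            raise ValueError("a CV training fold lost one class; reduce n_folds")
        sc = Scaler(method=scaling).fit(Xtr)
        core = _opls_core(sc.transform(Xtr), ytr - ytr.mean(), n_ortho)
        Ev = sc.transform(X[val])
        for k in range(core["W_o"].shape[1]):
            t_o = Ev @ core["W_o"][:, k]
            Ev = Ev - np.outer(t_o, core["P_o"][:, k])
        yhat = (Ev @ core["w"]) * core["q"] + ytr.mean()
        press += float(((y01[val] - yhat) ** 2).sum())
        ssy += float(((y01[val] - ytr.mean()) ** 2).sum())
    return press, ssy


def oplsda_fit(
    X,
    y,
    n_ortho: int | str = "auto",
    n_folds: int = 7,
    scaling: str = "pareto",
    seed: int = 0,
    max_ortho: int = 5,
) -> OplsModel:
    """Fit OPLS-DA on samples x features ``X`` against binary labels ``y``.

    ``n_ortho="auto"`` adds orthogonal components while the cross-validated
    Q² improves by more than 0.01. Q² uses deterministic stratified folds;
    scaling is re-estimated inside each fold.
    """
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y01, classes = _encode_y(y)
    if X.shape[0] != y01.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples")

    if n_ortho == "auto":
        chosen = 0
        press, ssy = _cv_press(X, y01, 0, n_folds, scaling, seed)
        best_q2 = 1.0 - press / ssy
        best = (press, ssy)
        for cand in range(1, max_ortho + 1):
            press, ssy = _cv_press(X, y01, cand, n_folds, scaling, seed)
            q2 = 1.0 - press / ssy
            if q2 > best_q2 + 0.01:
                chosen, best_q2, best = cand, q2, (press, ssy)
            else:
                break
        press, ssy = best
    else:
        chosen = int(n_ortho)
        press, ssy = _cv_press(X, y01, chosen, n_folds, scaling, seed)
        best_q2 = 1.0 - press / ssy

    scaler = Scaler(method=scaling).fit(X, columns=feature_names)
    Xs = scaler.transform(X)
    y_mean = float(y01.mean())
    core = _opls_core(Xs, y01 - y_mean, chosen)
    sstot = float((Xs**2).sum())
    r2x = 1.0 - float((core["E"] ** 2).sum()) / sstot if sstot > 0 else 0.0
    yc = y01 - y_mean
    r2y = 1.0 - float(((yc - core["t"] * core["q"]) ** 2).sum()) / float((yc**2).sum())
    yhat = core["t"] * core["q"] + y_mean
    thr = 0.5 * (yhat[y01 == 0].mean() + yhat[y01 == 1].mean())
    return OplsModel(
        scaler=scaler,
        y_mean=y_mean,
        classes_=classes,
        w=core["w"],
        t=core["t"],
        p=core["p"],
        q=core["q"],
        W_o=core["W_o"],
        T_o=core["T_o"],
        P_o=core["P_o"],
        E=core["E"],
        r2x=r2x,
        r2y=r2y,
        q2=best_q2,
        n_ortho=core["n_ortho"],
        n_folds=n_folds,
        seed=seed,
        cv_press=press,
        cv_ssy=ssy,
        n_samples=X.shape[0],
        threshold=float(thr),
        feature_names=scaler.columns if feature_names is not None else None,
    )


def opls_predict(model: OplsModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Predictive scores t and continuous class predictions for new samples."""
    if isinstance(X_new, pd.DataFrame) and model.feature_names is not None:
        missing = [c for c in model.scaler.columns or [] if c not in X_new.columns]
        if missing:
            raise ValueError(f"new data lacks training features: {missing[:10]}")
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature mismatch: model expects {model.scaler.mean_.shape[0]} raw features, "
            f"got {X_new.shape[1]}"
        )
    E = model.scaler.transform(X_new)
    for k in range(model.W_o.shape[1]):
        t_o = E @ model.W_o[:, k]
        E = E - np.outer(t_o, model.P_o[:, k])
    t = E @ model.w
    return t, t * model.q + model.y_mean


def splot(model: OplsModel, X_scaled) -> pd.DataFrame:
    """S-plot coordinates: per feature, cov(t, x_j) and corr(t, x_j).

    ``X_scaled`` must be the scaled training matrix (as produced by
    ``model.scaler.transform``). Zero-variance features have undefined
    correlation and are excluded with a note.
    """
    Xs = np.asarray(X_scaled, dtype=float)
    t = model.t
    tc = t - t.mean()
    Xc = Xs - Xs.mean(axis=0)
    n = Xs.shape[0]
    p_cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    ok = sx > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-variance feature(s) excluded from S-plot")
    p_corr = np.full_like(p_cov, np.nan)
    p_corr[ok] = p_cov[ok] / (sx[ok] * st)
    names = model.feature_names if model.feature_names is not None else list(range(Xs.shape[1]))
    out = pd.DataFrame({"p_cov": p_cov, "p_corr": p_corr}, index=pd.Index(names, name="feature"))
    return out[ok].sort_values("p_corr", ascending=False)


@dataclass
class PermutationReport:
    records: pd.DataFrame  # columns: corr, r2y, q2
    true_r2y: float
    true_q2: float
    q2_intercept: float
    r2y_intercept: float
    passed: bool

    def to_dict(self) -> dict:
        return {
            "n_perm": int(len(self.records)),
            "true_r2y": self.true_r2y,
            "true_q2": self.true_q2,
            "q2_intercept": self.q2_intercept,
            "r2y_intercept": self.r2y_intercept,
            "max_perm_q2": float(self.records["q2"].max()),
            "passed": self.passed,
        }


def permutation_test(
    X,
    y,
    n_perm: int = 200,
    seed: int = 0,
    n_folds: int = 7,
    scaling: str = "pareto",
    n_ortho: int | None = None,
) -> PermutationReport:
    """Random label-permutation validation.

    Refits the model on ``n_perm`` permuted label vectors (identity
    permutations are redrawn) recording corr(y_perm, y), R²Y and Q², and
    passes when every permuted Q² lies below the true Q² and the regression
    intercept of permuted Q² on |corr| stays below the true Q².
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    X = np.asarray(X, dtype=float)
    y01, _ = _encode_y(y)
    true = oplsda_fit(
        X, y01, n_ortho="auto" if n_ortho is None else n_ortho,
        n_folds=n_folds, scaling=scaling, seed=seed,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        yp = rng.permutation(y01)
        while np.array_equal(yp, y01):
            yp = rng.permutation(y01)
        m = oplsda_fit(X, yp, n_ortho=true.n_ortho, n_folds=n_folds, scaling=scaling, seed=seed)
        rows.append({"corr": float(np.corrcoef(yp, y01)[0, 1]), "r2y": m.r2y, "q2": m.q2})
    rec = pd.DataFrame(rows)

    def intercept(col: str) -> float:
        fit = stats.linregress(rec["corr"].abs(), rec[col])
        return float(fit.intercept)

    q2_int = intercept("q2")
    r2_int = intercept("r2y")
    passed = bool((rec["q2"] < true.q2).all() and q2_int < true.q2)
    return PermutationReport(rec, true.r2y, true.q2, q2_int, r2_int, passed)


def cv_anova(model: OplsModel) -> tuple[float, int, int, float]:
    """CV-ANOVA on the cross-validated residuals.

    F = ((SSY - PRESS) / A) / (PRESS / (n - A - 1)) where A = 1 + n_ortho is
    the number of model components (the convention used here; published
    degree-of-freedom conventions differ and the one applied is reported
    with the output). PRESS >= SSY yields F <= 0 and p = 1.
    """
    A = 1 + model.n_ortho
    n = model.n_samples
    df1, df2 = A, n - A - 1
    if df2 <= 0:
        raise ValueError("too few samples for CV-ANOVA degrees of freedom")
    F = ((model.cv_ssy - model.cv_press) / df1) / (model.cv_press / df2)
    if F <= 0:
        return float(F), df1, df2, 1.0
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def predict_and_roc(model: OplsModel, X_new, y_true_new):
    """Score held-out samples and compute the ROC curve and its AUC.

    Returns (scores, class_calls, roc_table, auc); the positive class is the
    second training class and the decision threshold is the training-score
    class-mean midpoint.
    """
    _, yhat = opls_predict(model, X_new)
    ytrue = np.asarray(y_true_new)
    pos = model.classes_[1]
    y01 = (ytrue == pos).astype(int) if ytrue.dtype != float else (ytrue == 1).astype(int)
    if np.unique(y01).size < 2:
        raise ValueError("y_true_new must contain both classes for a ROC curve")
    fpr, tpr, thresholds = roc_curve(y01, yhat)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    calls = np.where(yhat >= model.threshold, model.classes_[1], model.classes_[0])
    return yhat, calls, roc, float(_auc(fpr, tpr))


def plsda_vip(X, y_multi, n_components: int = 2, scaling: str = "pareto"):
    """PLS-DA on dummy-coded classes with VIP scores.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ); the
    mean of VIP² over features is 1 by construction, and VIP > 1 marks a
    variable as contributing more than average to the discrimination.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_multi)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("plsda_vip needs >= 2 classes")
    Y = (y[:, None] == classes[None, :]).astype(float)
    scaler = Scaler(method=scaling).fit(X, columns=names)
    Xs = scaler.transform(X)
    n_components = min(n_components, Xs.shape[1], X.shape[0] - 1)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Y - Y.mean(axis=0))
    W = pls.x_weights_  # (p, A), unit columns
    T = pls.x_scores_
    Q = pls.y_loadings_  # (g, A)
    ssy = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(W.shape[1])])
    p = W.shape[0]
    wnorm2 = (W**2) / (W**2).sum(axis=0)
    vip = np.sqrt(p * (wnorm2 * ssy).sum(axis=1) / ssy.sum())
    idx = scaler.columns if names is not None else list(range(p))
    return pd.Series(vip, index=pd.Index(idx, name="feature"), name="vip"), pls
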