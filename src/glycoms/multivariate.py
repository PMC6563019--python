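"""Discriminant modelling: UV scaling, PCA overview, OPLS-DA, validation.

The central model is orthogonal projections to latent structures
discriminant analysis (OPLS-DA) for a two-class response.  Variation in
the unit-variance-scaled data matrix X is split into a single predictive
component (t, p, w) aligned with the class vector y and ``n_ortho``
orthogonal components (T_o, P_o, W_o) capturing structured variation
uncorrelated with y:

    X = t p' + T_o P_o' + E,      y = t q + f

Each orthogonal component is extracted by taking the PLS weight
w ∝ X'y, its loading p = X't/(t't), removing the y-predictive direction
w_o ∝ p − (w'p/w'w) w, and deflating X by t_o p_o' with t_o = X w_o.  By
construction t_o'y = 0 and the final predictive score is exactly
orthogonal to every orthogonal score.

Model quality is summarized by R2X (fraction of X sum of squares captured
by all components), R2Y (fraction of y variance explained) and Q2
(cross-validated predictive ability, 1 − PRESS/TSS); Q2 > 0.5 is the
conventional reliability bar for this kind of serum profiling model.

The API follows the fitted-model convention: construct
``OPLSDA(X, y, n_ortho=1)`` (or ``PCA(X)``), call ``.fit()`` and work with
the returned Results object (scores, loadings, metrics, ``predict``,
``summary``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingParams", "uv_scale_fit", "uv_scale_apply",
    "PCA", "PCAResults", "OPLSDA", "OPLSDAResults",
    "cross_validate", "select_n_ortho", "make_split", "SplitSpec",
    "hotelling_ellipse", "Ellipse",
]


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScalingParams:
    """Training-set column means and sds for unit-variance scaling."""

    mean: pd.Series
    sd: pd.Series
    kept: pd.Index          # columns with nonzero variance

    def apply(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = self.kept.difference(X.columns)
        if len(missing):
            raise ValueError(f"missing features: {list(missing)[:5]}{'...' if len(missing) > 5 else ''}")
        Z = X[self.kept]
        return (Z - self.mean[self.kept]) / self.sd[self.kept]


def uv_scale_fit(X: pd.DataFrame) -> tuple[ScalingParams, pd.DataFrame]:
    """Mean-center and scale every column to unit (sample) variance.

    Zero-variance columns cannot be scaled; they are dropped with a
    warning and recorded in the returned params.
    """
    X = _as_frame(X)
    if len(X) < 2:
        raise ValueError("unit-variance scaling needs >= 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = X.columns[sd > 0]
    if len(kept) < len(X.columns):
        warnings.warn(f"dropping {len(X.columns) - len(kept)} zero-variance feature(s)",
                      stacklevel=2)
    params = ScalingParams(mean=mean, sd=sd, kept=kept)
    return params, params.apply(X)


def uv_scale_apply(params: ScalingParams, X: pd.DataFrame) -> pd.DataFrame:
    return params.apply(_as_frame(X))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


# ---------------------------------------------------------------------------
# PCA


class PCA:
    """Principal component analysis by singular value decomposition.

    Input is expected already scaled; the model re-centers defensively so
    score columns have zero mean.  ``fit()`` returns :class:`PCAResults`.
    """

    def __init__(self, X, n_components: int = 2, center: bool = True):
        self.X = _as_frame(X)
        n, p = self.X.shape
        if not 1 <= n_components <= min(n - 1, p):
            raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
        self.n_components = n_components
        self.center = center

    def fit(self) -> "PCAResults":
        Z = self.X.to_numpy(dtype=float)
        if self.center:
            Z = Z - Z.mean(axis=0)
        if not np.isfinite(Z).all():
            raise ValueError("PCA input contains non-finite values")
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        k = self.n_components
        U, s, Vt = U[:, :k], s[:k], Vt[:k]
        # deterministic sign: largest-|loading| element of each component positive
        for j in range(k):
            i = np.argmax(np.abs(Vt[j]))
            if Vt[j, i] < 0:
                Vt[j] *= -1
                U[:, j] *= -1
        total_ss = (Z ** 2).sum()
        evr = s ** 2 / total_ss if total_ss > 0 else np.zeros(k)
        scores = pd.DataFrame(U * s, index=self.X.index,
                              columns=[f"PC{j+1}" for j in range(k)])
        loadings = pd.DataFrame(Vt.T, index=self.X.columns, columns=scores.columns)
        return PCAResults(model=self, scores=scores, loadings=loadings,
                          explained_variance_ratio=evr)


@dataclass
class PCAResults:
    model: PCA
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def summary(self) -> str:
        lines = ["PCA results", f"  samples: {self.scores.shape[0]}  features: {self.loadings.shape[0]}"]
        for j, v in enumerate(self.explained_variance_ratio):
            lines.append(f"  PC{j+1}: {100 * v:.1f}% of variance")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# OPLS-DA


class OPLSDA:
    """Two-class OPLS discriminant model.

    Parameters
    ----------
    X : DataFrame or array, samples x features
        Raw feature matrix; scaled internally unless ``scale=False`` (then
        X must already be centered and unit-variance scaled).
    y : array-like
        Two-class labels; anything with exactly two distinct values
        (strings, 0/1, ±1).  Internally encoded {0,1} and centered; the
        lexicographically larger label is the positive class.
    n_ortho : int
        Number of orthogonal components to remove before the final
        predictive component.
    """

    def __init__(self, X, y, n_ortho: int = 1, scale: bool = True):
        self.X = _as_frame(X)
        y = pd.Series(np.asarray(y).ravel(), index=self.X.index)
        classes = sorted(pd.unique(y.astype(str)))
        if len(classes) != 2:
            raise ValueError(f"y must have exactly two classes, got {classes}")
        if n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.y_labels = y
        self.classes_ = classes
        self.y01 = (y.astype(str) == classes[1]).astype(float)
        self.n_ortho = n_ortho
        self.scale = scale

    def fit(self) -> "OPLSDAResults":
        if self.scale:
            scaling, Z = uv_scale_fit(self.X)
        else:
            scaling = None
            Z = self.X
        features = Z.columns
        Xm = Z.to_numpy(dtype=float)
        y = self.y01.to_numpy() - self.y01.mean()
        ss_x_total = float((Xm ** 2).sum())
        ss_y_total = float((y ** 2).sum())
        if ss_y_total == 0:
            raise ValueError("response has no variance")

        Xd = Xm.copy()
        W_o, P_o, T_o = [], [], []
        for _ in range(self.n_ortho):
            w = Xd.T @ y
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                break
            w /= w_norm
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                break
            p = Xd.T @ t / tt
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12 * np.linalg.norm(p):
                break  # no orthogonal variation left
            w_o /= n_o
            t_o = Xd @ w_o
            tt_o = t_o @ t_o
            if tt_o == 0:
                break
            p_o = Xd.T @ t_o / tt_o
            Xd = Xd - np.outer(t_o, p_o)
            W_o.append(w_o); P_o.append(p_o); T_o.append(t_o)

        # final predictive component on the deflated matrix
        w = Xd.T @ y
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            raise ValueError("X carries no covariance with the response")
        w /= w_norm
        t = Xd @ w
        tt = float(t @ t)
        p = Xd.T @ t / tt
        q = float(y @ t / tt)

        resid_y = y - t * q
        r2y = 1.0 - float(resid_y @ resid_y) / ss_y_total
        ss_model = tt * float(p @ p) + sum(
            float(to @ to) * float(po @ po) for to, po in zip(T_o, P_o)
        )
        r2x = ss_model / ss_x_total if ss_x_total > 0 else 0.0

        T_o_arr = np.column_stack(T_o) if T_o else np.empty((len(t), 0))
        return OPLSDAResults(
            model=self,
            features=features,
            scaling=scaling,
            w=pd.Series(w, index=features, name="w"),
            p=pd.Series(p, index=features, name="p"),
            q=q,
            t=pd.Series(t, index=Z.index, name="t_pred"),
            W_o=pd.DataFrame(np.column_stack(W_o) if W_o else np.empty((len(features), 0)),
                             index=features,
                             columns=[f"wo{k+1}" for k in range(len(W_o))]),
            P_o=pd.DataFrame(np.column_stack(P_o) if P_o else np.empty((len(features), 0)),
                             index=features,
                             columns=[f"po{k+1}" for k in range(len(P_o))]),
            T_o=pd.DataFrame(T_o_arr, index=Z.index,
                             columns=[f"to{k+1}" for k in range(T_o_arr.shape[1])]),
            r2x=float(r2x),
            r2y=float(r2y),
            n_ortho=len(T_o),
            y_mean=float(self.y01.mean()),
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model: weights, loadings, scores and fit metrics."""

    model: OPLSDA
    features: pd.Index
    scaling: ScalingParams | None
    w: pd.Series            # predictive weight (unit norm)
    p: pd.Series            # predictive X loading
    q: float                # y loading
    t: pd.Series            # predictive score
    W_o: pd.DataFrame       # orthogonal weights
    P_o: pd.DataFrame       # orthogonal loadings
    T_o: pd.DataFrame       # orthogonal scores
    r2x: float
    r2y: float
    n_ortho: int
    y_mean: float
    q2: float | None = None

    # -- prediction --------------------------------------------------------
    def transform(self, Xnew) -> tuple[pd.Series, pd.DataFrame]:
        """Scores for new raw samples: scale with training params, strip the
        orthogonal components, project on the predictive weight."""
        Xnew = _as_frame(Xnew)
        if self.scaling is not None:
            Z = self.scaling.apply(Xnew)
        else:
            missing = self.features.difference(Xnew.columns)
            if len(missing):
                raise ValueError(f"missing features: {list(missing)[:5]}")
            Z = Xnew[self.features]
        M = Z.to_numpy(dtype=float)
        to_cols = {}
        for k in range(self.W_o.shape[1]):
            w_o = self.W_o.iloc[:, k].to_numpy()
            p_o = self.P_o.iloc[:, k].to_numpy()
            t_o = M @ w_o
            M = M - np.outer(t_o, p_o)
            to_cols[self.T_o.columns[k]] = t_o
        t_new = pd.Series(M @ self.w.to_numpy(), index=Xnew.index, name="t_pred")
        return t_new, pd.DataFrame(to_cols, index=Xnew.index)

    def predict(self, Xnew) -> pd.DataFrame:
        """Predict new samples.

        Returns a frame with predictive/orthogonal scores, the continuous
        prediction ``y_hat`` on the {0,1} scale and the class call
        (threshold 0.5)."""
        t_new, T_o_new = self.transform(Xnew)
        y_hat = t_new * self.q + self.y_mean
        calls = np.where(y_hat >= 0.5, self.model.classes_[1], self.model.classes_[0])
        out = pd.DataFrame({"t_pred": t_new, "y_hat": y_hat, "class": calls})
        return pd.concat([out, T_o_new], axis=1)

    # -- validation --------------------------------------------------------
    def cross_val_q2(self, k: int = 7, seed: int = 0) -> float:
        q2 = cross_validate(self.model.X, self.model.y_labels, n_ortho=self.model.n_ortho,
                            k=k, seed=seed, scale=self.model.scale)
        self.q2 = q2
        return q2

    def summary(self) -> str:
        n, p = self.model.X.shape
        counts = self.model.y_labels.astype(str).value_counts()
        lines = [
            "OPLS-DA results",
            "=" * 46,
            f"  samples: {n} ({counts.to_dict()})",
            f"  features: {len(self.features)} (of {p} supplied)",
            f"  components: 1 predictive + {self.n_ortho} orthogonal",
            f"  R2X: {self.r2x:.3f}",
            f"  R2Y: {self.r2y:.3f}",
        ]
        if self.q2 is not None:
            lines.append(f"  Q2(cum): {self.q2:.3f}  ({'reliable' if self.q2 > 0.5 else 'below 0.5 reliability bar'})")
        return "\n".join(lines)

    def to_json(self, path=None):
        import json
        obj = {
            "classes": self.model.classes_,
            "n_ortho": self.n_ortho,
            "r2x": self.r2x,
            "r2y": self.r2y,
            "q2": self.q2,
            "q": self.q,
            "y_mean": self.y_mean,
            "features": list(map(str, self.features)),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "W_o": self.W_o.to_numpy().tolist(),
            "P_o": self.P_o.to_numpy().tolist(),
            "scaling": None if self.scaling is None else {
                "mean": self.scaling.mean[self.scaling.kept].tolist(),
                "sd": self.scaling.sd[self.scaling.kept].tolist(),
            },
        }
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh)


def oplsda_fit(Xscaled, y, n_ortho: int = 1) -> OPLSDAResults:
    """Functional form operating on an already-scaled matrix."""
    return OPLSDA(Xscaled, y, n_ortho=n_ortho, scale=False).fit()


def pca_fit(Xscaled, n_components: int = 2) -> PCAResults:
    return PCA(Xscaled, n_components=n_components).fit()


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(y: pd.Series, k: int, seed: int) -> np.ndarray:
    """Round-robin fold assignment within each class, seed-shuffled order."""
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    y_arr = y.astype(str).to_numpy()
    for cls in np.unique(y_arr):
        idx = np.where(y_arr == cls)[0]
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(X, y, n_ortho: int = 1, k: int = 7, seed: int = 0,
                   scale: bool = True) -> float:
    """k-fold cross-validated Q2(cum) = 1 − PRESS / TSS.

    Folds are class-stratified round-robin after a seeded within-class
    shuffle; each fold's predictions come from a model fitted (including
    any scaling) on the remaining folds only.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = _as_frame(X)
    y = pd.Series(np.asarray(y).ravel(), index=X.index)
    classes = sorted(pd.unique(y.astype(str)))
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    k = min(k, y.astype(str).value_counts().min())
    if k < 2:
        raise ValueError("smallest class too small for cross-validation")
    folds = _stratified_folds(y, k, seed)

    y01 = (y.astype(str) == classes[1]).astype(float).to_numpy()
    press = 0.0
    for f in range(k):
        test = folds == f
        train = ~test
        if len(np.unique(y.astype(str).to_numpy()[train])) < 2:  # pragma: no cover
            raise ValueError(f"fold {f} leaves a single-class training set")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fold-local zero-variance drops
            res = OPLSDA(X.iloc[train], y.iloc[train], n_ortho=n_ortho, scale=scale).fit()
            pred = res.predict(X.iloc[test])
        press += float(((y01[test] - pred["y_hat"].to_numpy()) ** 2).sum())
    tss = float(((y01 - y01.mean()) ** 2).sum())
    return 1.0 - press / tss


def select_n_ortho(X, y, candidates=range(4), k: int = 7, seed: int = 0,
                   scale: bool = True) -> tuple[int, dict[int, float]]:
    """Pick n_ortho maximizing cross-validated Q2 (ties -> fewest components)."""
    q2s = {a: cross_validate(X, y, n_ortho=a, k=k, seed=seed, scale=scale)
           for a in candidates}
    best = max(sorted(q2s), key=lambda a: q2s[a])
    return best, q2s


# ---------------------------------------------------------------------------
# train/test split


@dataclass(frozen=True)
class SplitSpec:
    train_ids: tuple
    test_ids: tuple
    fraction: float
    seed: int


def make_split(labels: pd.Series, fraction: float = 0.8, seed: int = 0,
               train_counts: dict | None = None) -> SplitSpec:
    """Class-stratified random train/test split.

    Per-class training count is round(fraction * class size) unless
    ``train_counts`` pins explicit counts per class label.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be strictly inside (0, 1)")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, grp in labels.groupby(labels.astype(str)):
        ids = grp.index.to_numpy()
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = (train_counts or {}).get(cls, int(round(fraction * len(ids))))
        n_train = min(max(n_train, 1), len(ids) - 1)
        ids = rng.permutation(ids)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitSpec(train_ids=tuple(train), test_ids=tuple(test),
                     fraction=fraction, seed=seed)


# ---------------------------------------------------------------------------
# Hotelling's T2 ellipse


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse of a 2-D score cloud (Hotelling's T2)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the first axis

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, s], [-s, c]])
        loc = pts @ R.T
        a, b = self.semi_axes
        return (loc[:, 0] / a) ** 2 + (loc[:, 1] / b) ** 2 <= 1.0


def hotelling_ellipse(scores, alpha: float = 0.05) -> Ellipse:
    """95% (by default) Hotelling's T2 ellipse of two score columns.

    The critical value is ``2 (n-1) / (n-2) * F_{2, n-2}(1-alpha)``; semi-axes
    are sqrt(eigenvalue * T2crit) of the score covariance.  As n grows this
    approaches the chi-square limit sqrt(chi2_{2}(1-alpha)) per unit sd.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    n = S.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    center = S.mean(axis=0)
    cov = np.cov(S, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    if np.min(evals) <= 0 or not np.isfinite(evals).all():
        raise ValueError("singular score covariance")
    t2crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(1.0 - alpha, 2, n - 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(evals * t2crit)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=(float(center[0]), float(center[1])),
                   semi_axes=(float(semi[0]), float(semi[1])), angle=angle)
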