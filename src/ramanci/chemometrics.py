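"""Latent-variable modelling for spectral matrices: NIPALS PCA and PLS1.

Both algorithms are implemented from scratch (they are the analytical core
of the multivariate crystallinity models), operate on mean-centered,
unscaled variables (spectra are already SNV-normalized), and extract
components one at a time with deflation. Cross-validation is *grouped*:
all spectra of one batch stay in one segment, so replicate spectra of a
batch can never leak between training and validation folds.

Conventions
-----------
* loadings / weights are unit-norm; the sign is fixed so each vector's
  largest-magnitude element is positive (reproducible fixtures);
* explained calibration variance per component is 100 * SS_component /
  total centered SS;
* validation variance is PRESS-based: 100 * (1 - PRESS_k / total SS of
  held-out rows), reported per component (increments of the cumulative
  curve).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConvergenceError,
    FitError,
    MetricError,
    ValidationError,
)
from .spectra_io import SpectrumSet

__all__ = [
    "MODEL_WINDOW",
    "DataMatrix",
    "PCAModel",
    "PLSModel",
    "CVSegments",
    "build_data_matrix",
    "grouped_segments",
    "nipals_pca",
    "pca_cv_variance",
    "pls1_fit",
    "pls_predict",
    "pls_cv_rmse",
    "regression_metrics",
    "correlation_loadings",
    "select_factors",
    "save_pls_model",
    "load_pls_model",
]

#: Wavenumber window (cm^-1) used as X variables in the multivariate models.
MODEL_WINDOW = (250.0, 1500.0)


# ---------------------------------------------------------------------------
# data matrix
# ---------------------------------------------------------------------------

@dataclass
class DataMatrix:
    """Observations (spectra) by variables (wavenumbers) with group labels."""

    X: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        n, p = self.X.shape
        if n < 2 or p < 2:
            raise ValidationError(f"data matrix must be at least 2x2, got {n}x{p}")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("data matrix contains non-finite values")
        if self.wavenumbers.size != p:
            raise ValidationError("wavenumber labels do not match column count")
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("column wavenumbers must be strictly monotonic")
        if len(self.sample_ids) != n or len(self.groups) != n:
            raise ValidationError("row labels do not match row count")


def build_data_matrix(
    spectra: SpectrumSet,
    groups=None,
    window: tuple[float, float] = MODEL_WINDOW,
) -> DataMatrix:
    """Assemble a model matrix from pre-processed spectra, restricted to the
    modelling window (default 250-1500 cm^-1)."""
    if len(spectra) < 2:
        raise ValidationError("need at least 2 spectra")
    wn = spectra.common_axis
    lo, hi = min(window), max(window)
    mask = (wn >= lo) & (wn <= hi)
    if mask.sum() < 2:
        raise ValidationError(f"fewer than 2 wavenumbers inside window {window}")
    X = spectra.intensity_matrix()[:, mask]
    ids = [s.sample_id for s in spectra]
    if groups is None:
        groups = ids
    return DataMatrix(X, wn[mask], ids, list(groups))


def _as_xy(X) -> np.ndarray:
    if isinstance(X, DataMatrix):
        return X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    return X


# ---------------------------------------------------------------------------
# grouped cross-validation segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVSegments:
    """A partition of row indices into segments that never split a group."""

    segments: tuple[tuple[int, ...], ...]
    grouping_key: str = "batch"

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for seg in self.segments:
            if not seg:
                raise ValidationError("empty CV segment")
            if seen & set(seg):
                raise ValidationError("CV segments overlap")
            seen |= set(seg)

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)


def grouped_segments(groups, n_segments: int | None = None) -> CVSegments:
    """Partition rows into CV segments keeping whole groups together.

    With ``n_segments=None`` (auto) there is one segment per distinct
    group, in first-appearance order. With fewer segments than groups,
    whole groups are dealt round-robin over the segments in group order.
    """
    groups = list(groups)
    order: list = []
    members: dict = {}
    for i, g in enumerate(groups):
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)
    if len(order) < 2:
        raise ValidationError("grouped CV needs >= 2 distinct groups")
    if n_segments is None:
        n_segments = len(order)
    if n_segments > len(order):
        raise ValidationError(
            f"n_segments={n_segments} exceeds the number of groups ({len(order)})"
        )
    if n_segments < 2:
        raise ValidationError("need at least 2 segments")
    bins: list[list[int]] = [[] for _ in range(n_segments)]
    for k, g in enumerate(order):
        bins[k % n_segments].extend(members[g])
    return CVSegments(tuple(tuple(b) for b in bins))


# ---------------------------------------------------------------------------
# NIPALS PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean-centered principal-component model (NIPALS)."""

    means: np.ndarray
    loadings: np.ndarray            # (k, p), unit-norm rows
    scores: np.ndarray              # (n, k)
    explained_cal: np.ndarray       # (k,) percent of centered SS
    explained_val: np.ndarray | None = None   # (k,) PRESS-based, if computed
    total_ss: float = 0.0

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, Xnew) -> np.ndarray:
        Xc = _as_xy(Xnew) - self.means
        return Xc @ self.loadings.T


def _fix_sign(vec: np.ndarray) -> float:
    """Return +-1 so that the largest-magnitude element of vec is positive."""
    i = int(np.argmax(np.abs(vec)))
    return 1.0 if vec[i] >= 0 else -1.0


def nipals_pca(
    X,
    n_components: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> PCAModel:
    """NIPALS principal component analysis with deflation.

    Components are extracted sequentially: iterate p = X't/t't
    (normalized), t = Xp until the score vector's relative change falls
    below ``tol``, then deflate X := X - t p'.
    """
    Xm = _as_xy(X)
    n, p = Xm.shape
    kmax = min(n - 1, p)
    if not (1 <= n_components <= kmax):
        raise ValidationError(
            f"n_components must be in [1, {kmax}] for a {n}x{p} matrix"
        )
    means = Xm.mean(axis=0)
    E = Xm - means
    total_ss = float(np.sum(E * E))
    if total_ss == 0:
        raise FitError("matrix has zero centered variance")
    loadings = np.zeros((n_components, p))
    scores = np.zeros((n, n_components))
    expl = np.zeros(n_components)
    for k in range(n_components):
        # start from the column with the largest residual variance
        t = E[:, int(np.argmax(np.sum(E * E, axis=0)))].copy()
        if np.allclose(t, 0):
            raise ConvergenceError(
                f"residual matrix is zero before component {k + 1}; "
                "requested more components than the data's rank"
            )
        for _ in range(max_iter):
            pvec = E.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = E @ pvec
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        else:
            raise ConvergenceError(
                f"NIPALS did not converge for component {k + 1} "
                f"within {max_iter} iterations"
            )
        sign = _fix_sign(pvec)
        pvec, t = pvec * sign, t * sign
        E = E - np.outer(t, pvec)
        loadings[k] = pvec
        scores[:, k] = t
        expl[k] = 100.0 * float(t @ t) / total_ss
    return PCAModel(means=means, loadings=loadings, scores=scores,
                    explained_cal=expl, total_ss=total_ss)


def pca_cv_variance(X, segments: CVSegments, n_components: int) -> np.ndarray:
    """PRESS-based explained validation variance per component (percent).

    Each segment is held out in turn; a PCA is fitted on the remaining
    rows and the held-out rows are projected on its loadings. The
    cumulative validation variance with k components is
    100 * (1 - PRESS_k / SS), accumulated over segments; the returned
    array holds its per-component increments (aligned with
    ``explained_cal``).
    """
    Xm = _as_xy(X)
    n = Xm.shape[0]
    if len(segments) < 2:
        raise ValidationError("cross-validation needs >= 2 segments")
    press = np.zeros(n_components)
    total = 0.0
    for seg in segments:
        seg = np.asarray(seg, dtype=int)
        train = np.setdiff1d(np.arange(n), seg)
        if train.size < 2:
            raise ValidationError("a training fold has fewer than 2 rows")
        model = nipals_pca(Xm[train], min(n_components, min(train.size - 1,
                                                            Xm.shape[1])))
        Ec = Xm[seg] - model.means
        total += float(np.sum(Ec * Ec))
        R = Ec.copy()
        for k in range(n_components):
            if k < model.n_components:
                t = R @ model.loadings[k]
                R = R - np.outer(t, model.loadings[k])
            press[k] += float(np.sum(R * R))
    if total == 0:
        raise MetricError("held-out rows have zero variance about training means")
    cum = 100.0 * (1.0 - press / total)
    return np.diff(np.concatenate([[0.0], cum]))


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Mean-centered univariate partial-least-squares regression model.

    Stores the weight/loading sequence and, for every factor count
    1..max_factors, the regression coefficient vector and calibration
    statistics, so predictions can be made with any truncation.
    """

    x_means: np.ndarray
    y_mean: float
    weights: np.ndarray             # (p, k)
    x_loadings: np.ndarray          # (p, k)
    y_loadings: np.ndarray          # (k,)
    scores: np.ndarray              # (n, k)
    coefs: np.ndarray               # (k, p): row a-1 = coefficients with a factors
    fitted: np.ndarray              # (k, n)
    rmsec: np.ndarray               # (k,)
    explained_cal: np.ndarray       # (k,) % of y variance
    bias_cal: np.ndarray            # (k,)
    wavenumbers: np.ndarray | None = None
    rmsecv: np.ndarray | None = None
    stats: dict = field(default_factory=dict)

    @property
    def max_factors(self) -> int:
        return self.weights.shape[1]


def pls1_fit(X, y, max_factors: int, wavenumbers=None) -> PLSModel:
    """PLS1 by the classical NIPALS sequence.

    Per factor: w ∝ X'y (unit norm), t = Xw, p = X't/t't, q = y't/t't,
    deflate X and y. For univariate y this coincides with the kernel
    algorithm. Coefficients for a factors: b_a = W_a (P_a' W_a)^{-1} q_a.
    """
    wn = None
    if isinstance(X, DataMatrix):
        wn = X.wavenumbers
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float)
    Xm = _as_xy(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if y.size != n:
        raise ValidationError(f"y has {y.size} entries for {n} rows of X")
    kmax = min(n - 1, p)
    if not (1 <= max_factors <= kmax):
        raise ValidationError(
            f"max_factors must be in [1, {kmax}] for a {n}x{p} matrix"
        )
    if np.ptp(y) == 0:
        raise FitError("y has zero variance")
    x_means = Xm.mean(axis=0)
    y_mean = float(y.mean())
    E = Xm - x_means
    f = y - y_mean
    W = np.zeros((p, max_factors))
    P = np.zeros((p, max_factors))
    q = np.zeros(max_factors)
    T = np.zeros((n, max_factors))
    coefs = np.zeros((max_factors, p))
    fitted = np.zeros((max_factors, n))
    rmsec = np.zeros(max_factors)
    expl = np.zeros(max_factors)
    bias = np.zeros(max_factors)
    for a in range(max_factors):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw == 0:
            raise FitError(
                f"X'y is zero at factor {a + 1}: no further covariance to model"
            )
        w /= nw
        sign = _fix_sign(w)
        w *= sign
        t = E @ w
        tt = float(t @ t)
        if tt == 0:
            raise FitError(f"zero score vector at factor {a + 1}")
        pvec = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
        b = W[:, : a + 1] @ np.linalg.solve(
            P[:, : a + 1].T @ W[:, : a + 1], q[: a + 1]
        )
        coefs[a] = b
        yhat = y_mean + (Xm - x_means) @ b
        fitted[a] = yhat
        m = regression_metrics(y, yhat)
        rmsec[a] = m["rmse"]
        expl[a] = m["explained_variance_pct"]
        bias[a] = m["bias"]
    return PLSModel(
        x_means=x_means, y_mean=y_mean, weights=W, x_loadings=P,
        y_loadings=q, scores=T, coefs=coefs, fitted=fitted, rmsec=rmsec,
        explained_cal=expl, bias_cal=bias, wavenumbers=wn,
    )


def pls_predict(model: PLSModel, Xnew, n_factors: int) -> np.ndarray:
    """Predict with the first ``n_factors`` factors; ``n_factors=0`` is the
    intercept-only model (the calibration y mean)."""
    wn = None
    if isinstance(Xnew, DataMatrix):
        wn = Xnew.wavenumbers
    Xm = _as_xy(Xnew)
    if Xm.shape[1] != model.x_means.size:
        raise ValidationError(
            f"Xnew has {Xm.shape[1]} variables; model expects {model.x_means.size}"
        )
    if wn is not None and model.wavenumbers is not None:
        if not np.array_equal(wn, model.wavenumbers):
            raise ValidationError(
                "wavenumber grid of Xnew does not match the model's training "
                "grid (no silent resampling)"
            )
    if not (0 <= n_factors <= model.max_factors):
        raise ValidationError(
            f"n_factors must be in [0, {model.max_factors}]"
        )
    if n_factors == 0:
        return np.full(Xm.shape[0], model.y_mean)
    b = model.coefs[n_factors - 1]
    return model.y_mean + (Xm - model.x_means) @ b


def pls_cv_rmse(X, y, segments: CVSegments, max_factors: int) -> np.ndarray:
    """Grouped segmented cross-validation RMSE per factor count (RMSECV)."""
    Xm = _as_xy(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    press = np.zeros(max_factors)
    for seg in segments:
        seg = np.asarray(seg, dtype=int)
        train = np.setdiff1d(np.arange(n), seg)
        kfit = min(max_factors, min(train.size - 1, Xm.shape[1]))
        model = pls1_fit(Xm[train], y[train], kfit)
        for a in range(1, max_factors + 1):
            yhat = pls_predict(model, Xm[seg], min(a, kfit))
            press[a - 1] += float(np.sum((yhat - y[seg]) ** 2))
    return np.sqrt(press / n)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def regression_metrics(y_ref, y_pred) -> dict:
    """RMSE, bias, explained variance (%) and Pearson r of predictions.

    ``explained_variance_pct = 100 * (1 - Var(resid)/Var(y))`` with n-1
    variances; a pure offset therefore still explains 100% of the
    variance, and shows up in the bias instead.
    """
    y = np.asarray(y_ref, dtype=float).ravel()
    yh = np.asarray(y_pred, dtype=float).ravel()
    if y.size != yh.size or y.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    resid = yh - y
    out = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "bias": float(np.mean(resid)),
    }
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        raise MetricError("reference values have zero variance")
    out["explained_variance_pct"] = 100.0 * (1.0 - float(np.var(resid, ddof=1)) / vy)
    vyh = float(np.var(yh, ddof=1))
    out["pearson_r"] = (
        float(np.corrcoef(y, yh)[0, 1]) if vyh > 0 else 0.0
    )
    return out


#: radii of the 50% and 100% explained-variance circles in a
#: correlation-loadings plot.
CORRELATION_RADII = (np.sqrt(0.5), 1.0)


def correlation_loadings(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of each (centered) X variable with each score.

    Returns ``(C, flags)``: C is (variables x factors) in [-1, 1]; a
    zero-variance variable gets correlation 0 and its flag set.
    """
    Xm = _as_xy(X)
    scores = model.scores
    if Xm.shape[0] != scores.shape[0]:
        raise ValidationError("X rows do not match the model's score rows")
    Xc = Xm - Xm.mean(axis=0)
    Tc = scores - scores.mean(axis=0)
    sx = np.sqrt(np.sum(Xc * Xc, axis=0))
    st = np.sqrt(np.sum(Tc * Tc, axis=0))
    flags = sx == 0
    sx_safe = np.where(flags, 1.0, sx)
    st_safe = np.where(st == 0, 1.0, st)
    C = (Xc.T @ Tc) / np.outer(sx_safe, st_safe)
    C[flags, :] = 0.0
    return np.clip(C, -1.0, 1.0), flags


def select_factors(cv_rmse, rule: str = "first-minimum", fixed_k: int | None = None,
                   rel_tol: float = 0.02) -> int:
    """Choose a factor count from per-factor validation RMSE.

    ``first-minimum`` (default): the smallest k after which the RMSE stops
    improving by more than ``rel_tol`` (2%) relative. ``global-minimum``:
    argmin. ``fixed``: return ``fixed_k`` regardless of the statistics.
    """
    r = np.asarray(cv_rmse, dtype=float).ravel()
    if r.size < 1:
        raise ValidationError("need statistics for at least one factor count")
    if rule == "fixed":
        if fixed_k is None:
            raise ValidationError("rule 'fixed' requires fixed_k")
        return int(fixed_k)
    if rule == "global-minimum":
        return int(np.argmin(r)) + 1
    if rule != "first-minimum":
        raise ValidationError(f"unknown factor-selection rule {rule!r}")
    for k in range(r.size - 1):
        if (r[k] - r[k + 1]) <= rel_tol * r[k]:
            return k + 1
    return int(r.size)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def save_pls_model(model: PLSModel, path: str | os.PathLike) -> None:
    doc = {
        "schema": "ramanci.pls_model", "schema_version": 1,
        "x_means": model.x_means.tolist(), "y_mean": model.y_mean,
        "weights": model.weights.tolist(), "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(), "coefs": model.coefs.tolist(),
        "rmsec": model.rmsec.tolist(),
        "explained_cal": model.explained_cal.tolist(),
        "bias_cal": model.bias_cal.tolist(),
        "rmsecv": None if model.rmsecv is None else model.rmsecv.tolist(),
        "wavenumbers": None if model.wavenumbers is None
        else model.wavenumbers.tolist(),
        "stats": model.stats,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_pls_model(path: str | os.PathLike) -> PLSModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != "ramanci.pls_model":
        raise ValidationError(f"{path}: not a PLS model file")
    coefs = np.asarray(doc["coefs"])
    k, n = coefs.shape[0], 0
    return PLSModel(
        x_means=np.asarray(doc["x_means"]), y_mean=float(doc["y_mean"]),
        weights=np.asarray(doc["weights"]), x_loadings=np.asarray(doc["x_loadings"]),
        y_loadings=np.asarray(doc["y_loadings"]),
        scores=np.zeros((n, k)), coefs=coefs,
        fitted=np.zeros((k, n)), rmsec=np.asarray(doc["rmsec"]),
        explained_cal=np.asarray(doc["explained_cal"]),
        bias_cal=np.asarray(doc["bias_cal"]),
        wavenumbers=None if doc.get("wavenumbers") is None
        else np.asarray(doc["wavenumbers"]),
        rmsecv=None if doc.get("rmsecv") is None else np.asarray(doc["rmsecv"]),
        stats=doc.get("stats", {}),
    )
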