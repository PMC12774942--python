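"""NIPALS PLS1 regression, segmented leave-one-out CV and validation metrics.

The calibration model is a single-response (PLS1) NIPALS decomposition on
mean-centered data.  Cross-validation leaves one averaged sample out per
segment and, by default, refits the entire pretreatment chain (including
OSC when enabled) inside each fold so that no held-out information leaks
into the transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import PreprocessOptions, PretreatmentRecord, preprocess_chain


@dataclass
class PLSModel:
    """A fitted PLS1 calibration.

    W (channels x A) are the orthonormal NIPALS weights, P the X-loadings,
    q the y-loadings, T (samples x A) the orthogonal scores, and b the
    compact regression vector: ``yhat = y_mean + (X - x_mean) @ b``.
    """

    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    T: np.ndarray
    b: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    A: int
    pretreatment: PretreatmentRecord | None = None

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P^T W)^{-1}; new-sample scores are (x - x_mean) @ R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def scores(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"channel mismatch: {X_new.shape[1]} vs model {self.x_mean.size}"
            )
        return (X_new - self.x_mean) @ self.rotation


def pls_fit(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Fit a PLS1 model with ``A`` latent variables by NIPALS deflation.

    Data are mean-centered internally.  For a single response the NIPALS
    weight step is closed-form (w proportional to X^T y), so no inner
    iteration is needed; X and y are deflated once per component.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError("X rows must match y length")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    A = int(A)
    if A < 1:
        raise ValueError("A must be >= 1")
    if n < A + 1:
        raise ValueError(f"need at least A+1={A + 1} samples, have {n}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    x_scale = max(np.abs(Xd).max(), 1e-300)
    for a in range(A):
        cov = Xd.T @ yd
        nc = np.linalg.norm(cov)
        if nc <= 1e-13 * x_scale * max(np.abs(yd).max(), 1e-300) * np.sqrt(n):
            raise np.linalg.LinAlgError(
                f"X is rank-deficient for {A} components (failed at {a + 1})"
            )
        w = cov / nc
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-26 * x_scale**2:
            raise np.linalg.LinAlgError(
                f"zero-variance score at component {a + 1}; reduce A"
            )
        pvec = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa

    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(W=W, P=P, q=q, T=T, b=b, x_mean=x_mean, y_mean=y_mean, A=A)


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations: y_mean + (X - x_mean) @ b."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"channel mismatch: {X_new.shape[1]} vs model {model.x_mean.size}"
        )
    return model.y_mean + (X_new - model.x_mean) @ model.b


def _nested_b(W, P, q, A):
    """Regression vector of the first-A-component submodel."""
    return W[:, :A] @ np.linalg.solve(P[:, :A].T @ W[:, :A], q[:A])


@dataclass
class CVResult:
    """Leave-one-out CV curve: per-A metrics, residuals and the chosen A."""

    per_A: list  # of dicts: A, rmsecv, r2cv, residuals
    chosen_A: int
    segments: list

    def rmsecv(self, A: int | None = None) -> float:
        A = self.chosen_A if A is None else A
        return next(d["rmsecv"] for d in self.per_A if d["A"] == A)

    def r2cv(self, A: int | None = None) -> float:
        A = self.chosen_A if A is None else A
        return next(d["r2cv"] for d in self.per_A if d["A"] == A)

    def residuals(self, A: int | None = None) -> np.ndarray:
        A = self.chosen_A if A is None else A
        return next(d["residuals"] for d in self.per_A if d["A"] == A)


def select_lvs(cv: CVResult, tau: float = 0.02) -> int:
    """Most parsimonious A whose RMSECV is within (1 + tau) of the minimum."""
    if not cv.per_A:
        raise ValueError("empty CV result")
    best = min(d["rmsecv"] for d in cv.per_A)
    for d in sorted(cv.per_A, key=lambda d: d["A"]):
        if d["rmsecv"] <= (1.0 + tau) * best:
            return d["A"]
    return cv.per_A[-1]["A"]  # pragma: no cover


def loocv(
    X_raw: np.ndarray,
    y: np.ndarray,
    A_max: int,
    options: PreprocessOptions = PreprocessOptions(),
    tau: float = 0.02,
    refit_pretreatment: bool = True,
) -> CVResult:
    """Segmented leave-one-out cross-validation on replicate-averaged spectra.

    One segment per sample: for each held-out sample the pretreatment
    chain (including OSC, when enabled) and the PLS model are refitted on
    the remaining samples, and the held-out spectrum is transformed
    through the fold's :class:`PretreatmentRecord` before prediction.
    ``refit_pretreatment=False`` is a fast mode that reuses the full-data
    pretreatment (mild leakage; off by default).

    Returns per-A RMSECV/R2CV curves with held-out residuals (observed
    minus predicted) and the A chosen by :func:`select_lvs`.
    """
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X_raw.shape[0]
    if n != y.size:
        raise ValueError("X rows must match y length")
    if n < A_max + 2:
        raise ValueError(f"A_max={A_max} too large for n={n} samples")

    if not refit_pretreatment:
        X_all, record_all = preprocess_chain(X_raw, y, options)

    preds = np.empty((n, A_max))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if refit_pretreatment:
            X_train, record = preprocess_chain(X_raw[mask], y[mask], options)
            x_test = record.transform(X_raw[i : i + 1])
        else:
            X_train, x_test = X_all[mask], X_all[i : i + 1]
        model = pls_fit(X_train, y[mask], A_max)
        xc = x_test - model.x_mean
        for A in range(1, A_max + 1):
            preds[i, A - 1] = model.y_mean + (
                xc @ _nested_b(model.W, model.P, model.q, A)
            ).item()

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    per_A = []
    for A in range(1, A_max + 1):
        res = y - preds[:, A - 1]
        rmsecv = float(np.sqrt(np.mean(res**2)))
        per_A.append(
            {
                "A": A,
                "rmsecv": rmsecv,
                "r2cv": 1.0 - float(np.sum(res**2)) / ss_tot,
                "residuals": res,
            }
        )
    cv = CVResult(per_A=per_A, chosen_A=1, segments=[[i] for i in range(n)])
    cv.chosen_A = select_lvs(cv, tau=tau)
    return cv


@dataclass(frozen=True)
class ValidationMetrics:
    """R-squared and RMSE (mg/g) of one evaluation set."""

    r2: float
    rmse: float
    n: int
    kind: str  # "calibration" | "cv" | "testset"


def evaluate(model: PLSModel, X: np.ndarray, y: np.ndarray, kind: str) -> ValidationMetrics:
    """R-squared and RMSE of the model on a (pretreated) evaluation set.

    R-squared is computed against the variance of the evaluated subset's
    own y (the common chemometrics-software convention).
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 samples to evaluate")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("zero variance in y: R-squared undefined")
    yhat = pls_predict(model, X)
    ss_res = float(np.sum((yhat - y) ** 2))
    return ValidationMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean((yhat - y) ** 2))),
        n=y.size,
        kind=kind,
    )
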