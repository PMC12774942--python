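"""Multivariate detection and quantification limits for PLS calibrations.

Two conceptually different frameworks are implemented.

Variance-leverage mLOD/mLOQ (IUPAC-consistent, after Allegrini & Olivieri)::

    mLOD = 3.3 * sqrt( sigma_x^2 * (1 + h0) / ||b||^2  +  h0 * sigma_y^2 )
    mLOQ = (10 / 3.3) * mLOD

with ``sigma_x^2`` the mean instrumental variance across wavelengths,
``h0`` the score-space leverage of the blank surrogate (the lowest
concentration calibration sample when no true blank exists), ``sigma_y^2``
the variance of the calibration concentrations, and ``b`` the PLS
regression vector.  The minimum variant uses the blank-surrogate leverage,
the maximum variant the largest leverage in the calibration set, and the
average is their midpoint.

Net-analyte-signal NAS-LOD/LOQ (after Lorber)::

    w_NAS    = w1 orthogonalized against the other latent variables' X-loadings
    NAS-LOD  = 3  * s_a / ||w_NAS||
    NAS-LOQ  = 10 * s_a / ||w_NAS||

with ``s_a`` the residual standard deviation of cross-validated
prediction.  ``||w_NAS||`` measures how much analyte-specific signal the
model isolates from the background; it is computed on LV1 to keep the
convention standardized (conservative when analyte variance is spread
over later LVs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pls import CVResult, PLSModel

MLOQ_FACTOR = 10.0 / 3.3
NAS_LOQ_FACTOR = 10.0 / 3.0

LOD_TABLE_COLUMNS = [
    "mLODmin", "mLODmax", "mLODavg",
    "mLOQmin", "mLOQmax", "mLOQavg",
    "NAS-LOD", "NAS-LOQ", "LVs",
]


def leverage(
    model: PLSModel, x0: np.ndarray, include_centering_term: bool = False
) -> float:
    """Score-space leverage h = t0^T (T^T T)^{-1} t0 of one spectrum.

    ``x0`` must be pretreated and on the model's channel grid; it is
    centered with the model's calibration mean and projected through the
    NIPALS rotation.  ``include_centering_term`` adds the 1/n constant of
    the affine hat matrix (off by default: pure score-space form).
    """
    t0 = model.scores(np.atleast_2d(x0))[0]
    TtT = model.T.T @ model.T
    try:
        h = float(t0 @ np.linalg.solve(TtT, t0))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular score covariance T^T T") from exc
    if include_centering_term:
        h += 1.0 / model.T.shape[0]
    return h


@dataclass(frozen=True)
class MLODInputs:
    """Ingredients of the variance-leverage mLOD formula.

    sigma_x2 : mean instrumental variance across wavelengths (AU^2)
    h0       : leverage of the blank surrogate
    h0_max   : maximum leverage across the calibration set
    sigma_y2 : variance of the calibration concentrations ((mg/g)^2)
    b_norm   : Euclidean norm of the PLS regression vector
    """

    sigma_x2: float
    h0: float
    h0_max: float
    sigma_y2: float
    b_norm: float

    def __post_init__(self) -> None:
        if self.sigma_x2 < 0 or self.sigma_y2 < 0:
            raise ValueError("variances must be >= 0")
        if not self.b_norm > 0:
            raise ValueError("degenerate model: ||b|| must be > 0")
        if not (0 <= self.h0 <= self.h0_max):
            raise ValueError("need 0 <= h0 <= h0_max")


def mlod(inputs: MLODInputs, which: str = "min") -> float:
    """Variance-leverage multivariate LOD (mg/g).

    ``which='min'`` uses the blank-surrogate leverage ``h0``;
    ``which='max'`` uses the worst-case calibration leverage ``h0_max``.
    """
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    h = inputs.h0 if which == "min" else inputs.h0_max
    return 3.3 * float(
        np.sqrt(inputs.sigma_x2 * (1.0 + h) / inputs.b_norm**2 + h * inputs.sigma_y2)
    )


def mloq(mlod_value: float) -> float:
    """mLOQ = (10/3.3) * mLOD, the fixed IUPAC 10-sigma/3.3-sigma ratio."""
    if mlod_value < 0:
        raise ValueError("mLOD must be >= 0")
    return MLOQ_FACTOR * mlod_value


def nas_vector(
    model: PLSModel, analyte_lv: int = 1, literal: bool = False
) -> np.ndarray:
    """Net-analyte-signal vector: the analyte LV weight stripped of the
    other latent variables' X-loading subspace.

    Default mode removes the least-squares projection of ``w`` onto the
    column space of the remaining loadings ``P_rest``, which guarantees
    ``P_rest^T w_NAS = 0`` even though NIPALS loadings are not orthonormal.
    ``literal=True`` instead evaluates the textbook one-step form
    ``w - P_rest (P_rest^T w)``, exact only for orthonormal loadings.
    """
    if not 1 <= analyte_lv <= model.A:
        raise ValueError(f"analyte_lv must be in 1..{model.A}")
    w = model.W[:, analyte_lv - 1]
    if model.A == 1:
        return w.copy()
    rest = [a for a in range(model.A) if a != analyte_lv - 1]
    P_rest = model.P[:, rest]
    if literal:
        w_nas = w - P_rest @ (P_rest.T @ w)
    else:
        coef, *_ = np.linalg.lstsq(P_rest, w, rcond=None)
        w_nas = w - P_rest @ coef
    if np.linalg.norm(w_nas) <= 1e-12 * np.linalg.norm(w):
        raise ValueError(
            "analyte weight lies in the span of the other loadings: "
            "no isolable net analyte signal"
        )
    return w_nas


def nas_lod(s_a: float, w_nas_norm: float) -> float:
    """NAS-LOD = 3 s_a / ||w_NAS|| (mg/g); +inf when the NAS vanishes."""
    if s_a < 0:
        raise ValueError("s_a must be >= 0")
    if w_nas_norm <= 1e-300:
        return float("inf")
    return 3.0 * s_a / w_nas_norm


def nas_loq(s_a: float, w_nas_norm: float) -> float:
    """NAS-LOQ = 10 s_a / ||w_NAS|| (mg/g); always (10/3) * NAS-LOD."""
    if s_a < 0:
        raise ValueError("s_a must be >= 0")
    if w_nas_norm <= 1e-300:
        return float("inf")
    return 10.0 * s_a / w_nas_norm


@dataclass(frozen=True)
class LODReport:
    """Both detection-limit frameworks for one calibration, in mg/g."""

    mlod_min: float
    mlod_max: float
    mlod_avg: float
    mloq_min: float
    mloq_max: float
    mloq_avg: float
    nas_lod: float
    nas_loq: float
    F: int
    osc_used: bool
    mlod_inputs: MLODInputs
    s_a: float
    rmsecv: float
    w_nas_norm: float

    def to_row(self) -> dict:
        return {
            "mLODmin": self.mlod_min,
            "mLODmax": self.mlod_max,
            "mLODavg": self.mlod_avg,
            "mLOQmin": self.mloq_min,
            "mLOQmax": self.mloq_max,
            "mLOQavg": self.mloq_avg,
            "NAS-LOD": self.nas_lod,
            "NAS-LOQ": self.nas_loq,
            "LVs": self.F,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_row()], columns=LOD_TABLE_COLUMNS)


def lod_report(
    model: PLSModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    cv: CVResult,
    sigma_x2_mode: str = "pretreated",
    replicate_variance: np.ndarray | None = None,
    analyte_lv: int = 1,
    osc_used: bool = False,
) -> LODReport:
    """Assemble both LOD/LOQ frameworks for a fitted calibration.

    ``X_cal`` is the pretreated calibration matrix the model was fitted
    on.  ``sigma_x2_mode`` chooses the instrumental-variance estimate:
    ``"pretreated"`` (default) averages the per-channel variance of the
    pretreated calibration matrix over channels; ``"replicate"`` averages
    the per-channel variance among replicate scans (pass
    ``replicate_variance``, e.g. from replicate averaging).  The blank
    surrogate is the calibration sample with the lowest reference
    concentration.  ``s_a`` is the standard deviation of the CV residuals
    at the model's number of LVs.
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()

    if sigma_x2_mode == "pretreated":
        sigma_x2 = float(np.mean(X_cal.var(axis=0, ddof=1)))
    elif sigma_x2_mode == "replicate":
        if replicate_variance is None:
            raise ValueError("replicate mode needs replicate_variance")
        sigma_x2 = float(np.mean(replicate_variance))
    else:
        raise ValueError("sigma_x2_mode must be 'pretreated' or 'replicate'")

    sigma_y2 = float(np.var(y_cal, ddof=1))
    b_norm = float(np.linalg.norm(model.b))
    levs = np.array([leverage(model, X_cal[i]) for i in range(X_cal.shape[0])])
    h0 = float(levs[int(np.argmin(y_cal))])
    h0_max = float(levs.max())
    # the blank surrogate need not sit at an extreme of the score cloud
    h0 = min(h0, h0_max)

    inputs = MLODInputs(sigma_x2, h0, h0_max, sigma_y2, b_norm)
    lo, hi = mlod(inputs, "min"), mlod(inputs, "max")

    res = cv.residuals(model.A)
    s_a = float(np.std(res, ddof=1))
    rmsecv = cv.rmsecv(model.A)
    wn = float(np.linalg.norm(nas_vector(model, analyte_lv=analyte_lv)))

    return LODReport(
        mlod_min=lo,
        mlod_max=hi,
        mlod_avg=0.5 * (lo + hi),
        mloq_min=mloq(lo),
        mloq_max=mloq(hi),
        mloq_avg=0.5 * (mloq(lo) + mloq(hi)),
        nas_lod=nas_lod(s_a, wn),
        nas_loq=nas_loq(s_a, wn),
        F=model.A,
        osc_used=osc_used,
        mlod_inputs=inputs,
        s_a=s_a,
        rmsecv=rmsecv,
        w_nas_norm=wn,
    )
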