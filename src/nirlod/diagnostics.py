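"""Latent-structure diagnostics linking detection limits to interpretability.

Three views of where the analyte lives inside the latent space:

* per-LV explained analyte (y) variance — compact analyte representation
  shows up as a dominant first latent variable;
* projection of a pure analyte standard spectrum onto the X-loadings —
  an external probe of analyte alignment with the model subspace;
* an LV-truncation study — both LOD frameworks recomputed at forced
  model sizes F, exposing their opposite dependence on complexity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lod import LOD_TABLE_COLUMNS, lod_report
from .pls import PLSModel, loocv, pls_fit
from .preprocess import PreprocessOptions, PretreatmentRecord, preprocess_chain

TRUNCATION_COLUMNS = ["F", "R2CV", "RMSECV"] + LOD_TABLE_COLUMNS[:-1] + ["s_a"]


def explained_y_variance_per_lv(model: PLSModel, y: np.ndarray) -> np.ndarray:
    """Fraction of centered-y variance explained by each latent variable.

    Because NIPALS scores are orthogonal the incremental residual-SS drop
    of LV a is (q_a^2 t_a^T t_a); fractions are nonnegative and telescope
    to the full model's R-squared of calibration.
    """
    y = np.asarray(y, dtype=float).ravel()
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("constant y: explained variance undefined")
    contrib = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    return contrib / ss_tot


@dataclass(frozen=True)
class PureProjection:
    """Per-LV coefficients of a pure standard regressed on the X-loadings."""

    coefficients: np.ndarray          # raw least-squares coefficients
    normalized: np.ndarray            # coefficients / norm of pretreated spectrum
    residual_norm_fraction: float     # part of the spectrum outside the LV span


def project_pure_spectrum(
    model: PLSModel, pure: np.ndarray, record: PretreatmentRecord | None = None
) -> PureProjection:
    """Project a pure analyte standard spectrum onto the model's loadings.

    The standard receives the identical pretreatment as the calibration
    spectra (``record.transform`` — stateful steps such as OSC are applied
    with calibration-fitted parameters, never refitted), is centered with
    the calibration mean, and is then regressed on the X-loading matrix by
    least squares (tolerant of non-orthogonal NIPALS loadings).
    Coefficients are reported raw and scaled by the pretreated spectrum's
    norm.
    """
    pure = np.asarray(pure, dtype=float).ravel()
    if pure.size != model.x_mean.size and record is None:
        raise ValueError(
            f"grid mismatch: spectrum has {pure.size} channels, "
            f"model expects {model.x_mean.size}"
        )
    x = record.transform(pure[None, :])[0] if record is not None else pure
    if x.size != model.x_mean.size:
        raise ValueError(
            f"grid mismatch after pretreatment: {x.size} vs {model.x_mean.size}"
        )
    xc = x - model.x_mean
    coef, *_ = np.linalg.lstsq(model.P, xc, rcond=None)
    norm = np.linalg.norm(x)
    resid = xc - model.P @ coef
    xc_norm = max(np.linalg.norm(xc), 1e-300)
    return PureProjection(
        coefficients=coef,
        normalized=coef / max(norm, 1e-300),
        residual_norm_fraction=float(np.linalg.norm(resid) / xc_norm),
    )


def truncation_study(
    X_raw: np.ndarray,
    y: np.ndarray,
    A_values,
    options: PreprocessOptions = PreprocessOptions(),
    sigma_x2_mode: str = "pretreated",
    replicate_variance: np.ndarray | None = None,
    refit_pretreatment: bool = True,
) -> pd.DataFrame:
    """Recompute both LOD frameworks at forced model sizes F.

    For each F in ``A_values`` the model is truncated to F latent
    variables and RMSECV, the mLOD/mLOQ triplets, NAS-LOD/LOQ and s_a are
    re-evaluated (cross-validation residuals at F come from a single CV
    run at max(F)).  Returns one row per F.
    """
    A_values = sorted(int(a) for a in A_values)
    if len(set(A_values)) != len(A_values):
        raise ValueError("A_values must be distinct")
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    y = np.asarray(y, dtype=float).ravel()

    cv = loocv(X_raw, y, max(A_values), options, refit_pretreatment=refit_pretreatment)
    X_pre, _ = preprocess_chain(X_raw, y, options)

    rows = []
    for F in A_values:
        model = pls_fit(X_pre, y, F)
        rep = lod_report(
            model, X_pre, y, cv,
            sigma_x2_mode=sigma_x2_mode,
            replicate_variance=replicate_variance,
            osc_used=options.osc,
        )
        row = {"F": F, "R2CV": cv.r2cv(F), "RMSECV": cv.rmsecv(F)}
        row.update({k: v for k, v in rep.to_row().items() if k != "LVs"})
        row["s_a"] = rep.s_a
        rows.append(row)
    return pd.DataFrame(rows, columns=TRUNCATION_COLUMNS)
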