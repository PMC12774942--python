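"""Spectral pretreatment chain: derivative -> scatter correction -> OSC.

The chain order is fixed (Savitzky-Golay second derivative, then SNV or
MSC scatter correction, then optional orthogonal signal correction, then
mean-centering inside the regression step) and every stateful parameter —
the MSC reference spectrum, the OSC weight/loading vectors — is captured
in a :class:`PretreatmentRecord` so held-out and future spectra receive
*exactly* the calibration-fitted transformation.  Refitting OSC on test
data would leak information; the record makes that impossible by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

_CONST_ROW_RTOL = 1e-12


class DegenerateSpectrumError(ValueError):
    """A spectrum is constant (zero variance) where variance is required."""


def sg_second_derivative(
    spectra: np.ndarray, window: int = 9, polyorder: int = 2
) -> np.ndarray:
    """Savitzky-Golay second derivative of each row.

    Interior channels use the centered ``window``-point filter; the
    ``(window - 1) / 2`` channels at each edge are evaluated from the
    polynomial fitted to the nearest full window, so the channel count and
    grid alignment are preserved.  The derivative is taken with respect to
    the channel index (unit spacing).
    """
    window = int(window)
    polyorder = int(polyorder)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(
            f"window must be odd and > polyorder (got window={window}, "
            f"polyorder={polyorder})"
        )
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] < window:
        raise ValueError(f"need at least {window} channels, have {X.shape[1]}")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=2, delta=1.0,
        axis=1, mode="interp",
    )


def _row_sds(X: np.ndarray) -> np.ndarray:
    return X.std(axis=1, ddof=1)


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: center and unit-scale each row.

    Each output row has mean 0 and sample (n-1) standard deviation 1,
    removing additive offsets and multiplicative gain per spectrum.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    sds = _row_sds(X)
    scale = np.maximum(np.abs(X).max(axis=1), 0.0)
    bad = np.where(sds <= _CONST_ROW_RTOL * np.maximum(scale, 1e-300))[0]
    if bad.size:
        raise DegenerateSpectrumError(
            f"constant spectrum in row(s) {bad.tolist()}: SNV undefined"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sds[:, None]


def msc(spectra: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference (x ~ a + b*ref, ordinary
    least squares) and replaced by (x - a)/b.  Default reference is the
    column-mean spectrum of the input.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= _CONST_ROW_RTOL * max(np.abs(ref).max(), 1e-300) ** 2 * ref.size:
        raise ValueError("MSC reference spectrum has zero variance")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# Orthogonal signal correction
# ---------------------------------------------------------------------------

@dataclass
class PretreatmentRecord:
    """Ordered pretreatment steps plus all state needed to re-apply them.

    ``steps`` is an ordered list of ``(name, params)`` pairs; the order is
    always derivative -> scatter correction -> OSC -> centering for the
    steps that are present.  ``msc_reference`` and the OSC weight/loading/
    score arrays hold the calibration-fitted state.
    """

    steps: list = field(default_factory=list)
    msc_reference: np.ndarray | None = None
    osc_weights: np.ndarray | None = None   # channels x k
    osc_loadings: np.ndarray | None = None  # channels x k
    osc_scores: np.ndarray | None = None    # calibration samples x k

    _ORDER = ("sg_second_derivative", "snv", "msc", "osc", "center")

    def __post_init__(self) -> None:
        names = [s[0] for s in self.steps]
        ranks = [self._ORDER.index(n) for n in names if n in self._ORDER]
        if ranks != sorted(ranks):
            raise ValueError(f"pretreatment steps out of order: {names}")

    @property
    def has_osc(self) -> bool:
        return self.osc_weights is not None

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        """Apply the recorded chain to new spectra (no refitting)."""
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        for name, params in self.steps:
            if name == "sg_second_derivative":
                X = sg_second_derivative(X, **params)
            elif name == "snv":
                X = snv(X)
            elif name == "msc":
                X = msc(X, reference=self.msc_reference)
            elif name == "osc":
                X = osc_apply(self, X)
            elif name == "center":
                pass  # centering is owned by the regression model
            else:
                raise ValueError(f"unknown pretreatment step {name!r}")
        return X

    def to_json(self) -> str:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return json.dumps(
            {
                "steps": [[n, p] for n, p in self.steps],
                "msc_reference": arr(self.msc_reference),
                "osc_weights": arr(self.osc_weights),
                "osc_loadings": arr(self.osc_loadings),
                "osc_scores": arr(self.osc_scores),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PretreatmentRecord":
        d = json.loads(text)

        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            steps=[(n, p) for n, p in d["steps"]],
            msc_reference=arr(d["msc_reference"]),
            osc_weights=arr(d["osc_weights"]),
            osc_loadings=arr(d["osc_loadings"]),
            osc_scores=arr(d["osc_scores"]),
        )


def osc_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 1,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PretreatmentRecord:
    """Fit orthogonal signal correction (Wold-style NIPALS).

    For each component: start from the dominant principal-component score
    of the (internally centered) matrix, iterate orthogonalization of the
    score against y with a least-squares weight update until the score is
    stable, then deflate ``X <- X - t p^T``.  The weight vector solves
    ``X w = t`` exactly, which makes the out-of-sample correction
    (:func:`osc_apply`) reproduce the calibration deflation and be
    idempotent.

    Returns a :class:`PretreatmentRecord` holding the fitted weights,
    loadings and removed scores.  The corrected calibration matrix is
    recovered with ``osc_apply(record, X)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size or n < 3:
        raise ValueError("X rows must match y length and be >= 3")
    if np.std(y) <= 1e-12 * max(np.abs(y).max(), 1e-300):
        raise ValueError("y is constant; OSC is undefined")
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if n_components >= rank:
        raise ValueError(
            f"n_components ({n_components}) must be < rank(centered X) ({rank})"
        )
    yc = y - y.mean()
    yty = yc @ yc

    Xd = Xc.copy()
    weights, loadings, scores = [], [], []
    for _ in range(n_components):
        # dominant PC score as the starting direction
        U, s, _ = np.linalg.svd(Xd, full_matrices=False)
        t = U[:, 0] * s[0]
        for _ in range(max_iter):
            t_orth = t - yc * (yc @ t) / yty
            w, *_ = np.linalg.lstsq(Xd, t_orth, rcond=None)
            t_new = Xd @ w
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        # final pass: orthogonalize, then re-solve so Xd @ w == t exactly
        t_orth = t - yc * (yc @ t) / yty
        w, *_ = np.linalg.lstsq(Xd, t_orth, rcond=None)
        t = Xd @ w
        nw = np.linalg.norm(w)
        if nw <= 0:
            raise ValueError("OSC found no removable orthogonal component")
        w = w / nw
        t = t / nw
        tt = t @ t
        if tt <= 1e-300:
            raise ValueError("OSC component has zero variance")
        pvec = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        weights.append(w)
        loadings.append(pvec)
        scores.append(t)

    return PretreatmentRecord(
        steps=[("osc", {"n_components": n_components})],
        osc_weights=np.column_stack(weights),
        osc_loadings=np.column_stack(loadings),
        osc_scores=np.column_stack(scores),
    )


def osc_apply(record: PretreatmentRecord, X_new: np.ndarray) -> np.ndarray:
    """Remove the calibration-fitted OSC component(s) from new spectra.

    Computes ``X - (X w / w^T w) p^T`` per stored component.  Applying the
    correction to already-corrected data is a no-op (idempotent), and
    applying it to the calibration matrix reproduces the fit's deflation.
    """
    if record.osc_weights is None:
        raise ValueError("record holds no fitted OSC weights")
    X = np.atleast_2d(np.asarray(X_new, dtype=float)).copy()
    W, P = record.osc_weights, record.osc_loadings
    if X.shape[1] != W.shape[0]:
        raise ValueError(
            f"channel mismatch: spectra have {X.shape[1]} channels, "
            f"OSC was fitted on {W.shape[0]}"
        )
    for k in range(W.shape[1]):
        w, pvec = W[:, k], P[:, k]
        t = X @ w / (w @ w)
        X = X - np.outer(t, pvec)
    return X


# ---------------------------------------------------------------------------
# Chain driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessOptions:
    """Switches for the standardized pretreatment chain."""

    derivative: bool = True
    sg_window: int = 9
    sg_polyorder: int = 2
    scatter: str = "snv"  # "snv" | "msc" | "none"
    osc: bool = False
    osc_components: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in ("snv", "msc", "none"):
            raise ValueError("scatter must be 'snv', 'msc' or 'none'")


def preprocess_chain(
    spectra: np.ndarray,
    y: np.ndarray | None = None,
    options: PreprocessOptions = PreprocessOptions(),
) -> tuple[np.ndarray, PretreatmentRecord]:
    """Fit-and-apply the pretreatment chain on a calibration set.

    Steps run in the fixed order derivative -> scatter correction -> OSC;
    OSC (which needs ``y``) is fitted on this data only.  Returns the
    pretreated matrix and the :class:`PretreatmentRecord` that re-applies
    the identical transformation to unseen spectra via ``record.transform``.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    steps: list = []
    msc_ref = None
    if options.derivative:
        X = sg_second_derivative(X, options.sg_window, options.sg_polyorder)
        steps.append(
            ("sg_second_derivative",
             {"window": options.sg_window, "polyorder": options.sg_polyorder})
        )
    if options.scatter == "snv":
        X = snv(X)
        steps.append(("snv", {}))
    elif options.scatter == "msc":
        msc_ref = X.mean(axis=0)
        X = msc(X, reference=msc_ref)
        steps.append(("msc", {}))
    osc_record = None
    if options.osc:
        if y is None:
            raise ValueError("OSC requires the reference concentrations y")
        osc_record = osc_fit(X, y, n_components=options.osc_components)
        X = osc_apply(osc_record, X)
        steps.append(("osc", {"n_components": options.osc_components}))
    return X, PretreatmentRecord(
        steps=steps,
        msc_reference=msc_ref,
        osc_weights=None if osc_record is None else osc_record.osc_weights,
        osc_loadings=None if osc_record is None else osc_record.osc_loadings,
        osc_scores=None if osc_record is None else osc_record.osc_scores,
    )
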