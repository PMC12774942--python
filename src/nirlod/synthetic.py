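"""Synthetic NIR diffuse-reflectance calibration data.

The generator produces spectra with the statistical structure that the
downstream calibration and detection-limit analysis assumes:

* Beer-like linear mixing of broad Gaussian analyte and matrix bands,
* matrix components with log-normal concentrations, at least one of which
  co-varies with the analyte (so orthogonal signal correction has both
  y-correlated and y-orthogonal variance to separate),
* multiplicative gain plus additive baseline (offset + slope) scatter —
  exactly the structure SNV/MSC are designed to remove, with larger
  scatter for intact than for milled material,
* instrument degradation: Gaussian line-shape convolution, truncation to
  the device window, resampling to the device channel grid, and additive
  per-channel noise,
* triplicate replicate scans differing in scatter realization and noise.

All randomness flows from a single seed, so equal seeds give bit-identical
datasets.  The noiseless pure analyte spectra on the instrument grid are
returned alongside the data (``SpectraSet.pure_spectra``) for use by the
latent-structure diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import ReferenceTable, SpectraSet
from .instruments import InstrumentProfile

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# Band tables: (center cm^-1, fwhm cm^-1, amplitude AU per mg/g).
# Vitexin and isovitexin are positional isomers: their band sets overlap
# heavily and are only slightly shifted, which is the analytically hard
# scenario the package targets.  Amplitudes put a 10 mg/g analyte load at
# a few 1e-2 AU against a matrix background of order 1 AU.
VITEXIN_BANDS = [
    (4310.0, 90.0, 2.2e-3),   # aromatic C-H combination
    (4705.0, 120.0, 2.8e-3),  # O-H/C-O combination
    (5230.0, 150.0, 1.6e-3),  # phenolic O-H
    (5890.0, 140.0, 1.9e-3),  # C-H first overtone
    (6920.0, 220.0, 1.1e-3),  # O-H first overtone
]
ISOVITEXIN_BANDS = [
    (4340.0, 95.0, 2.1e-3),
    (4670.0, 115.0, 2.6e-3),
    (5265.0, 150.0, 1.5e-3),
    (5855.0, 140.0, 2.0e-3),
    (6960.0, 220.0, 1.0e-3),
]

# Plant-matrix components: cellulose/hemicellulose-like, protein-like and
# water-like backgrounds with broad strong bands (absorbance of order 1).
_CELLULOSE_BANDS = [
    (4280.0, 220.0, 0.45),
    (4760.0, 260.0, 0.38),
    (5600.0, 400.0, 0.22),
    (6300.0, 500.0, 0.15),
]
_PROTEIN_BANDS = [
    (4590.0, 200.0, 0.30),
    (4860.0, 240.0, 0.25),
    (5750.0, 380.0, 0.18),
]
_WATER_BANDS = [
    (5155.0, 260.0, 0.55),
    (6900.0, 420.0, 0.35),
]


@dataclass(frozen=True)
class MatrixComponent:
    """A co-varying background constituent with log-normal abundance.

    ``corr_with_analyte`` is the correlation rho between the latent normal
    driving this component's abundance and the (standardized) total analyte
    concentration; nonzero rho creates the y-correlated confounding that
    orthogonal signal correction is meant to strip.
    """

    bands: list
    log_mean: float = 0.0
    log_sd: float = 0.2
    corr_with_analyte: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated calibration campaign.

    Defaults reproduce the reference scenario: 50 plant-material samples,
    two isomeric analytes spanning 0.3-10 mg/g, triplicate scans, milled
    presentation, and one matrix confounder correlated with the analytes.
    """

    n_samples: int = 50
    concentration_range: tuple[float, float] = (0.3, 10.0)
    analyte_bands: dict = field(
        default_factory=lambda: {
            "vitexin": list(VITEXIN_BANDS),
            "isovitexin": list(ISOVITEXIN_BANDS),
        }
    )
    matrix_components: tuple = (
        MatrixComponent(_CELLULOSE_BANDS, log_mean=0.0, log_sd=0.15),
        MatrixComponent(_PROTEIN_BANDS, log_mean=0.0, log_sd=0.25,
                        corr_with_analyte=0.6),
        MatrixComponent(_WATER_BANDS, log_mean=0.0, log_sd=0.20),
    )
    # scatter realization per replicate scan (milled material)
    gain_sd: float = 0.05
    offset_sd: float = 0.02
    slope_sd: float = 0.02
    sample_state: str = "milled"  # "milled" | "intact"
    intact_scatter_multiplier: float = 2.5
    intact_noise_multiplier: float = 2.0
    n_replicates: int = 3
    native_grid: tuple[float, float, float] = (10700.0, 3900.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.concentration_range
        if not (0 < lo < hi):
            raise ValueError("concentration_range must satisfy 0 < low < high")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sample_state not in ("milled", "intact"):
            raise ValueError("sample_state must be 'milled' or 'intact'")
        for bands in self.analyte_bands.values():
            for c, fwhm, amp in bands:
                if not np.isfinite(c):
                    raise ValueError("band centers must be finite")
                if fwhm <= 0:
                    raise ValueError("band fwhm must be > 0")
                if amp < 0:
                    raise ValueError("band amplitudes must be >= 0")

    @property
    def scatter_scale(self) -> float:
        return self.intact_scatter_multiplier if self.sample_state == "intact" else 1.0

    @property
    def noise_scale(self) -> float:
        return self.intact_noise_multiplier if self.sample_state == "intact" else 1.0


def native_wavenumbers(config: SyntheticConfig) -> np.ndarray:
    """Descending native simulation grid (cm^-1) for a config."""
    high, low, step = config.native_grid
    return np.arange(high, low - 0.5 * step, -step)


def make_pure_spectrum(bands, wavenumbers) -> np.ndarray:
    """Sum of Gaussian bands evaluated on a wavenumber grid.

    Each band is ``(center cm^-1, fwhm cm^-1, amplitude)``; an empty band
    list yields the all-zero spectrum.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.size == 0:
        raise ValueError("wavenumber grid is empty")
    spectrum = np.zeros_like(wn)
    for center, fwhm, amplitude in bands:
        if fwhm <= 0:
            raise ValueError("band fwhm must be > 0")
        if not np.isfinite(center):
            raise ValueError("band center must be finite")
        sigma = fwhm * _FWHM_TO_SIGMA
        spectrum += amplitude * np.exp(-0.5 * ((wn - center) / sigma) ** 2)
    return spectrum


def apply_instrument(
    spectrum: np.ndarray,
    native_grid: np.ndarray,
    profile: InstrumentProfile,
    rng: np.random.Generator | None = None,
    noise_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Degrade a native-grid spectrum to an instrument's view of it.

    Convolves with a Gaussian kernel of the profile's resolution FWHM,
    truncates to the profile window, resamples to the profile channel
    count, and adds per-channel Gaussian noise (``profile.noise_sd *
    noise_scale``; pass ``rng=None`` for the noiseless transfer function).

    Returns ``(instrument_grid, degraded_spectrum)`` with the grid in
    descending wavenumber order, entirely inside the profile range.
    """
    wn = np.asarray(native_grid, dtype=float)
    x = np.asarray(spectrum, dtype=float)
    if wn.size != x.size:
        raise ValueError("spectrum and native grid lengths differ")
    if wn.max() < profile.wn_high or wn.min() > profile.wn_low:
        raise ValueError(
            f"native grid [{wn.min():.0f}, {wn.max():.0f}] does not span the "
            f"profile range [{profile.wn_low:.0f}, {profile.wn_high:.0f}]"
        )
    spacing = np.abs(np.diff(wn))
    if not np.allclose(spacing, spacing[0]):
        raise ValueError("native grid must be uniformly spaced")
    sigma_channels = profile.resolution_fwhm * _FWHM_TO_SIGMA / spacing[0]
    blurred = gaussian_filter1d(x, sigma_channels, mode="nearest")

    out_grid = np.linspace(profile.wn_high, profile.wn_low, profile.n_channels)
    # np.interp needs ascending abscissae
    order = np.argsort(wn)
    resampled = np.interp(out_grid, wn[order], blurred[order])
    if rng is not None and profile.noise_sd > 0:
        resampled = resampled + rng.normal(
            0.0, profile.noise_sd * noise_scale, resampled.shape
        )
    return out_grid, resampled


def simulate_dataset(
    config: SyntheticConfig, profile: InstrumentProfile
) -> tuple[SpectraSet, ReferenceTable]:
    """Simulate a replicate-resolved calibration campaign on one instrument.

    Per replicate scan of sample i with analyte concentrations c and matrix
    abundances u::

        A = gain * (sum_k c_k * pure_k + sum_m u_m * matrix_m)
            + offset + slope * s(wavenumber)

    with ``s`` the wavenumber scaled to [0, 1], followed by instrument
    degradation (convolution, truncation, resampling, channel noise).
    Gain ~ N(1, gain_sd) truncated positive; offset and slope are
    zero-mean Gaussian; intact material scales all scatter sds and the
    channel noise up.

    Returns a :class:`SpectraSet` (one row per replicate scan, with
    ``replicate_of`` grouping and noiseless ``pure_spectra`` on the
    instrument grid) and the matching :class:`ReferenceTable` (one row per
    sample; columns vitexin, isovitexin, sum).
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(config.seed)
    wn_native = native_wavenumbers(config)
    lo, hi = config.concentration_range

    analytes = list(config.analyte_bands)
    pure_native = {
        name: make_pure_spectrum(bands, wn_native)
        for name, bands in config.analyte_bands.items()
    }
    matrix_native = [
        make_pure_spectrum(m.bands, wn_native) for m in config.matrix_components
    ]

    # reference concentrations, uniform over the calibration range
    conc = rng.uniform(lo, hi, size=(config.n_samples, len(analytes)))
    total = conc.sum(axis=1)
    z_total = (total - total.mean()) / max(total.std(), 1e-12)

    # matrix abundances: latent normal correlated with total analyte load
    abundances = np.empty((config.n_samples, len(config.matrix_components)))
    for j, comp in enumerate(config.matrix_components):
        rho = comp.corr_with_analyte
        z = rho * z_total + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(
            config.n_samples
        )
        abundances[:, j] = np.exp(comp.log_mean + comp.log_sd * z)

    sscale = config.scatter_scale
    s_coord = (wn_native - wn_native.min()) / (wn_native.max() - wn_native.min())

    rows, ids, groups = [], [], []
    width = len(str(config.n_samples))
    for i in range(config.n_samples):
        base = np.zeros_like(wn_native)
        for k, name in enumerate(analytes):
            base += conc[i, k] * pure_native[name]
        for j in range(len(config.matrix_components)):
            base += abundances[i, j] * matrix_native[j]
        sid = f"S{i + 1:0{width}d}"
        for r in range(config.n_replicates):
            gain = 0.0
            while gain <= 0:  # truncated-positive multiplicative gain
                gain = rng.normal(1.0, config.gain_sd * sscale)
            offset = rng.normal(0.0, config.offset_sd * sscale)
            slope = rng.normal(0.0, config.slope_sd * sscale)
            native = gain * base + offset + slope * s_coord
            grid, degraded = apply_instrument(
                native, wn_native, profile, rng=rng, noise_scale=config.noise_scale
            )
            rows.append(degraded)
            ids.append(f"{sid}_r{r + 1}")
            groups.append(sid)

    pure_on_grid = {}
    for name in analytes:
        grid, deg = apply_instrument(pure_native[name], wn_native, profile, rng=None)
        pure_on_grid[name] = deg
    pure_on_grid["sum"] = sum(pure_on_grid[name] for name in analytes)

    spectra = SpectraSet(
        wavenumbers=grid,
        absorbance=np.vstack(rows),
        sample_ids=ids,
        replicate_of=groups,
        instrument=profile.name,
        pure_spectra=pure_on_grid,
    )
    table = ReferenceTable(
        sample_ids=[f"S{i + 1:0{width}d}" for i in range(config.n_samples)],
        concentrations=_concentration_frame(conc, analytes, config.n_samples, width),
    )
    return spectra, table


def _concentration_frame(conc, analytes, n, width):
    import pandas as pd

    df = pd.DataFrame(
        conc,
        columns=analytes,
        index=[f"S{i + 1:0{width}d}" for i in range(n)],
    )
    if set(analytes) == {"vitexin", "isovitexin"}:
        df["sum"] = df["vitexin"] + df["isovitexin"]
    return df


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average replicate scans into one spectrum per physical sample.

    Returns one row per replicate group (channel-wise mean, groups in
    first-appearance order).  The pooled per-channel variance among
    replicates *before* averaging is kept as ``replicate_variance`` — a
    candidate estimate of purely instrumental variance for the
    detection-limit stage.
    """
    if spectra.replicate_of is None:
        raise ValueError("replicate grouping is required to average replicates")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, g in enumerate(spectra.replicate_of):
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(i)

    means, variances = [], []
    for g in order:
        idx = members[g]
        if len(idx) == 0:
            raise ValueError(f"replicate group {g!r} is empty")
        block = spectra.absorbance[idx]
        means.append(block.mean(axis=0))
        if len(idx) > 1:
            variances.append(block.var(axis=0, ddof=1))
    rep_var = np.mean(variances, axis=0) if variances else None

    return SpectraSet(
        wavenumbers=spectra.wavenumbers,
        absorbance=np.vstack(means),
        sample_ids=order,
        replicate_of=None,
        instrument=spectra.instrument,
        pure_spectra=spectra.pure_spectra,
        replicate_variance=rep_var,
    )
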