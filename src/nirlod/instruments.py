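"""Instrument profiles for simulated NIR acquisition.

A profile describes the spectral window, channel count, resolution
(FWHM of the Gaussian instrument line-shape used for convolution) and the
per-channel additive noise level of a device class.  Four built-in
profiles emulate a benchtop FT-NIR and three handheld spectrometers
commonly used for plant-material analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class InstrumentProfile:
    """Spectral window, sampling and noise of a simulated spectrometer.

    Parameters
    ----------
    name : str
        Device label, carried into generated :class:`~nirlod.containers.SpectraSet`.
    wn_high, wn_low : float
        Upper and lower wavenumber bound (cm^-1); ``wn_high > wn_low``.
    n_channels : int
        Number of recorded channels (>= 8).
    resolution_fwhm : float
        FWHM in cm^-1 of the Gaussian convolution kernel.
    noise_sd : float
        Standard deviation of additive per-channel Gaussian noise,
        in absorbance units.
    """

    name: str
    wn_high: float
    wn_low: float
    n_channels: int
    resolution_fwhm: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.wn_high > self.wn_low:
            raise ValueError(
                f"profile {self.name!r}: wn_high ({self.wn_high}) must exceed "
                f"wn_low ({self.wn_low})"
            )
        if self.n_channels < 8:
            raise ValueError(f"profile {self.name!r}: n_channels must be >= 8")
        if not self.resolution_fwhm > 0:
            raise ValueError(f"profile {self.name!r}: resolution_fwhm must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"profile {self.name!r}: noise_sd must be >= 0")

    @property
    def range(self) -> tuple[float, float]:
        """(high, low) wavenumber bounds in cm^-1, FT-NIR descending order."""
        return (self.wn_high, self.wn_low)


# Built-in device classes.  Ranges and channel counts follow the public
# specifications of the emulated instruments; noise levels are generator
# defaults reflecting the benchtop vs handheld signal-to-noise gap.
BUILTIN_PROFILES: dict[str, InstrumentProfile] = {
    # benchtop FT-NIR, 10000-4000 cm^-1 at 8 cm^-1
    "n500": InstrumentProfile("n500", 10000.0, 4000.0, 751, 8.0, 3e-4),
    # handheld LVF, 8000-4651 cm^-1, 128-pixel InGaAs array
    "micronir2200": InstrumentProfile("micronir2200", 8000.0, 4651.0, 128, 40.0, 1.2e-3),
    # handheld LVF, 10526-6060 cm^-1, 125 recorded wavelengths
    "micronir1700es": InstrumentProfile("micronir1700es", 10526.0, 6060.0, 125, 50.0, 8e-4),
    # handheld MEMS interferometer, 6250-4170 cm^-1, ~16 cm^-1 sampling
    "microphazir": InstrumentProfile("microphazir", 6250.0, 4170.0, 131, 16.0, 1.0e-3),
}


def get_profile(name: str) -> InstrumentProfile:
    """Look up a built-in profile by name (case-insensitive)."""
    key = name.lower()
    if key not in BUILTIN_PROFILES:
        raise KeyError(
            f"unknown instrument profile {name!r}; "
            f"available: {sorted(BUILTIN_PROFILES)}"
        )
    return BUILTIN_PROFILES[key]
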