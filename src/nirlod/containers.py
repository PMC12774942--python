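"""In-memory containers: spectra sets and reference-concentration tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANALYTES = ("vitexin", "isovitexin", "sum")


@dataclass
class SpectraSet:
    """A samples x channels absorbance matrix with its wavenumber axis.

    ``wavenumbers`` must be strictly monotone (descending by FT-NIR
    convention, but ascending is accepted).  ``replicate_of`` groups rows
    that are repeat scans of the same physical sample; ``None`` means the
    set is already replicate-averaged.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    replicate_of: list[str] | None = None
    instrument: str = ""
    # optional extras attached by the generator / replicate averaging:
    # noiseless pure-component spectra on this grid, per-channel replicate
    # variance of the averaged rows.
    pure_spectra: dict[str, np.ndarray] | None = None
    replicate_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be a 1-D vector")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("wavenumbers must be finite")
        d = np.diff(self.wavenumbers)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if self.absorbance.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[0]} rows but "
                f"{len(self.sample_ids)} sample ids"
            )
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} channels but the "
                f"wavenumber axis has {self.wavenumbers.size}"
            )
        if self.replicate_of is not None and len(self.replicate_of) != len(self.sample_ids):
            raise ValueError("replicate_of must align with sample_ids")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavenumbers.copy(),
            self.absorbance.copy(),
            list(self.sample_ids),
            list(self.replicate_of) if self.replicate_of is not None else None,
            self.instrument,
            dict(self.pure_spectra) if self.pure_spectra is not None else None,
            None if self.replicate_variance is None else self.replicate_variance.copy(),
        )

    def subset(self, indices) -> "SpectraSet":
        idx = np.asarray(indices)
        return SpectraSet(
            self.wavenumbers,
            self.absorbance[idx],
            [self.sample_ids[i] for i in idx],
            [self.replicate_of[i] for i in idx] if self.replicate_of is not None else None,
            self.instrument,
            self.pure_spectra,
        )


@dataclass
class ReferenceTable:
    """Per-sample reference concentrations (mg/g) with named analyte columns."""

    sample_ids: list[str]
    concentrations: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.concentrations, pd.DataFrame):
            self.concentrations = pd.DataFrame(
                self.concentrations, index=self.sample_ids
            )
        if len(self.sample_ids) != len(self.concentrations):
            raise ValueError("sample_ids and concentration rows must align")
        vals = self.concentrations.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("concentrations must be non-negative")
        cols = self.concentrations.columns
        if {"vitexin", "isovitexin", "sum"} <= set(cols):
            resid = np.abs(
                self.concentrations["sum"].to_numpy()
                - self.concentrations["vitexin"].to_numpy()
                - self.concentrations["isovitexin"].to_numpy()
            )
            if np.any(resid > 1e-9):
                raise ValueError("sum column must equal vitexin + isovitexin")

    def y(self, analyte: str) -> np.ndarray:
        """Concentration vector (mg/g) for one analyte column."""
        if analyte not in self.concentrations.columns:
            raise KeyError(
                f"analyte {analyte!r} not in table "
                f"(has {list(self.concentrations.columns)})"
            )
        return self.concentrations[analyte].to_numpy(dtype=float)

    def subset(self, indices) -> "ReferenceTable":
        idx = np.asarray(indices)
        return ReferenceTable(
            [self.sample_ids[i] for i in idx],
            self.concentrations.iloc[idx].copy(),
        )
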