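"""Containers for reflectance spectra.

A :class:`Spectrum` is a single reflectance trace on an ascending
wavelength axis (nm); a :class:`SpectraMatrix` is a stack of spectra
sharing one axis, the object every preprocessing and selection step
acts on.  CSV layout (shared with the synthetic generator): first
column sample id, second column concentration (mg/kg, may be empty),
remaining columns one per nanometre with the wavelength as header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "SpectraMatrix"]


@dataclass
class Spectrum:
    """One reflectance spectrum on a strictly increasing wavelength axis."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.reflectance.size} reflectance values"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectraMatrix:
    """Samples x wavelengths reflectance grid with one shared axis."""

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x wavelengths array")
        if self.values.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"{self.values.shape[1]} columns but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("one sample id per row required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.wavelengths.size

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.values[i])

    def with_values(self, values: np.ndarray) -> "SpectraMatrix":
        """New matrix on the same axis/ids with replaced reflectance values."""
        return SpectraMatrix(self.wavelengths, values, list(self.sample_ids))

    def band_index(self, nm: float) -> int:
        """Index of an on-grid wavelength; raises if `nm` is off the axis."""
        idx = int(np.argmin(np.abs(self.wavelengths - nm)))
        if not np.isclose(self.wavelengths[idx], nm):
            raise ValueError(f"wavelength {nm} nm is not on the axis")
        return idx

    # ---- CSV round trip -------------------------------------------------
    def to_csv(self, path, concentrations: np.ndarray | None = None) -> None:
        df = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        df.insert(0, "concentration", np.asarray(concentrations, dtype=float)
                  if concentrations is not None else np.nan)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> tuple["SpectraMatrix", np.ndarray | None]:
        """Read the package CSV layout; returns (matrix, concentrations or None)."""
        df = pd.read_csv(path)
        if df.shape[1] < 3 or df.columns[0] != "sample_id":
            raise ValueError(f"{path}: not a leafspec spectra CSV")
        wavelengths = np.array([float(c) for c in df.columns[2:]])
        mat = cls(wavelengths, df.iloc[:, 2:].to_numpy(float),
                  [str(s) for s in df["sample_id"]])
        conc = df["concentration"].to_numpy(float)
        return mat, (None if np.all(np.isnan(conc)) else conc)
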