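"""Wavelength grids and wavelength-indexed series.

A :class:`SpectralGrid` is the common currency of every optics stage: all
absorption, scattering and reflectance quantities are stored as values on a
shared, strictly increasing wavelength axis in nanometres. The visible
analysis band used throughout is 435–630 nm at 1-nm steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Limits of the visible band the instrument model supports (nm).
WAVELENGTH_MIN = 400.0
WAVELENGTH_MAX = 700.0

#: Default analysis band (nm).
BAND_LO = 435.0
BAND_HI = 630.0


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength axis in nm, restricted to 400–700 nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise ValueError(
                f"wavelengths must lie within [{WAVELENGTH_MIN:g}, "
                f"{WAVELENGTH_MAX:g}] nm, got [{wl[0]:g}, {wl[-1]:g}]"
            )
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    @classmethod
    def default(cls, lo: float = BAND_LO, hi: float = BAND_HI, step: float = 1.0) -> "SpectralGrid":
        """The default 435–630 nm analysis grid at 1-nm steps."""
        return cls(np.arange(lo, hi + 0.5 * step, step))

    def subsample(self, step_nm: float) -> "SpectralGrid":
        """Decimated copy with roughly ``step_nm`` spacing (keeps endpoints inside)."""
        wl = self.wavelengths
        stride = max(1, int(round(step_nm / np.median(np.diff(wl)))))
        return SpectralGrid(wl[::stride])


@dataclass
class Spectrum:
    """Values sampled on a :class:`SpectralGrid` (units documented by the owner)."""

    grid: SpectralGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"values shape {v.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        self.values = v

    def interp_to(self, grid: SpectralGrid) -> "Spectrum":
        """Linear interpolation onto ``grid``; raises if ``grid`` is not covered."""
        src = self.grid.wavelengths
        dst = grid.wavelengths
        if dst[0] < src[0] - 1e-9 or dst[-1] > src[-1] + 1e-9:
            raise ValueError(
                f"spectrum '{self.name}' covers [{src[0]:g}, {src[-1]:g}] nm, "
                f"cannot interpolate to [{dst[0]:g}, {dst[-1]:g}] nm"
            )
        return Spectrum(grid, np.interp(dst, src, self.values), name=self.name)

    def band_mean(self) -> float:
        """Wavelength-averaged value over the grid."""
        return float(np.mean(self.values))

    def to_frame(self, value_col: str = "value") -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.grid.wavelengths, value_col: self.values}
        )


def read_two_column_csv(path, value_col: str | None = None, name: str = "") -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV table as a :class:`Spectrum`."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    wl_col = df.columns[0]
    vcol = value_col if value_col is not None else df.columns[1]
    return Spectrum(SpectralGrid(df[wl_col].to_numpy()), df[vcol].to_numpy(), name=name)
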