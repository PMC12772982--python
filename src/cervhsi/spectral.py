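"""Wavelength grids, hypercubes, mean spectra and band-ratio tissue indices.

The central objects are :class:`WavelengthGrid` (a uniform band-center grid),
:class:`Hypercube` (an ``H x W x B`` reflectance array bound to a grid) and
:class:`BandRatioIndexDef` (a configurable two-window absorbance comparison
producing a per-pixel index map in ``[0, 1]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "BandRatioIndexDef",
    "IndexMap",
    "DEFAULT_INDEX_DEFS",
    "INDEX_NAMES",
    "build_grid",
    "absorbance",
    "mean_spectrum",
    "zscore_spectrum",
    "compute_index",
    "compute_all_indices",
    "region_mean_index",
]

ABSORBANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniformly spaced band centers ``start_nm + k * step_nm``, k = 0..n_bands-1."""

    start_nm: float
    step_nm: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")

    @property
    def centers(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    @property
    def end_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_bands - 1)

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of band centers within ``[lo_nm, hi_nm]`` (inclusive)."""
        c = self.centers
        idx = np.nonzero((c >= lo_nm - 1e-9) & (c <= hi_nm + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(
                f"no band centers in window [{lo_nm}, {hi_nm}] nm "
                f"(grid spans {self.start_nm}-{self.end_nm} nm)"
            )
        return idx


def build_grid(start_nm: float, step_nm: float, end_nm: float) -> WavelengthGrid:
    """Build a grid covering ``start_nm .. end_nm`` inclusive in ``step_nm`` steps.

    ``end_nm - start_nm`` must be an integer multiple of ``step_nm``.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if end_nm < start_nm:
        raise ValueError("end_nm must be >= start_nm")
    span = end_nm - start_nm
    k = span / step_nm
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"(end - start) = {span} nm is not divisible by step = {step_nm} nm"
        )
    return WavelengthGrid(start_nm=start_nm, step_nm=step_nm, n_bands=int(round(k)) + 1)


@dataclass
class Hypercube:
    """Reflectance cube: ``reflectance[row, col, band]`` in [0, 1] on a grid."""

    reflectance: np.ndarray
    grid: WavelengthGrid
    pixel_pitch_mm: float | None = None

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be a 3-D (H, W, B) array")
        if self.reflectance.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.reflectance.shape[2]} bands but grid has "
                f"{self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape  # type: ignore[return-value]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[:2]  # type: ignore[return-value]

    def restrict_window(self, lo_nm: float, hi_nm: float) -> "Hypercube":
        """Sub-cube keeping only bands whose centers fall in ``[lo_nm, hi_nm]``."""
        idx = self.grid.band_indices(lo_nm, hi_nm)
        sub = WavelengthGrid(
            start_nm=float(self.grid.centers[idx[0]]),
            step_nm=self.grid.step_nm,
            n_bands=int(idx.size),
        )
        return Hypercube(self.reflectance[:, :, idx], sub, self.pixel_pitch_mm)


def absorbance(reflectance: np.ndarray, floor: float = ABSORBANCE_FLOOR) -> np.ndarray:
    """``-log10(max(R, floor))`` — floored so zero reflectance stays finite."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    r = np.asarray(reflectance, dtype=np.float64)
    return -np.log10(np.maximum(r, floor))


def mean_spectrum(cube: Hypercube, mask: np.ndarray) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError(f"mask shape {mask.shape} != cube {cube.spatial_shape}")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return cube.reflectance[mask].mean(axis=0)


def zscore_spectrum(s: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize a spectrum to mean 0, sd 1 (population sd by default)."""
    s = np.asarray(s, dtype=np.float64)
    sd = s.std(ddof=ddof)
    if sd == 0:
        raise ValueError("constant spectrum cannot be z-scored")
    return (s - s.mean()) / sd


INDEX_NAMES = ("TWI", "THI", "StO2", "NIR")


@dataclass(frozen=True)
class BandRatioIndexDef:
    """Two-window absorbance comparison mapped onto [0, 1].

    The raw value is ``mean-absorbance(numerator) - mean-absorbance(denominator)``
    in ``difference`` mode, or their quotient in ``quotient`` mode; it is then
    affinely rescaled by ``scale = (raw_min, raw_max)`` and clipped to [0, 1].
    """

    name: str
    numerator_band: tuple[float, float]
    denominator_band: tuple[float, float]
    scale: tuple[float, float] = (-1.0, 1.0)
    mode: Literal["difference", "quotient"] = "difference"

    def __post_init__(self) -> None:
        if self.scale[0] >= self.scale[1]:
            raise ValueError("scale must satisfy raw_min < raw_max")
        if self.mode not in ("difference", "quotient"):
            raise ValueError(f"unknown mode {self.mode!r}")


# Default windows follow the published band layout of the imaging system the
# analysis emulates; exact vendor constants are proprietary, so everything is
# configurable.  Raw scales are symmetric so a spectrally flat pixel maps to 0.5.
DEFAULT_INDEX_DEFS: dict[str, BandRatioIndexDef] = {
    "TWI": BandRatioIndexDef("TWI", (955.0, 980.0), (880.0, 900.0)),
    "THI": BandRatioIndexDef("THI", (530.0, 590.0), (785.0, 825.0)),
    "StO2": BandRatioIndexDef("StO2", (570.0, 590.0), (740.0, 780.0)),
    "NIR": BandRatioIndexDef("NIR", (655.0, 735.0), (825.0, 925.0)),
}


@dataclass
class IndexMap:
    """Per-pixel tissue index in [0, 1]."""

    values: np.ndarray
    index_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("index map must be 2-D")


def compute_index(
    cube: Hypercube,
    index_def: BandRatioIndexDef,
    floor: float = ABSORBANCE_FLOOR,
) -> IndexMap:
    """Evaluate one band-ratio index for every pixel of the cube."""
    num_idx = cube.grid.band_indices(*index_def.numerator_band)
    den_idx = cube.grid.band_indices(*index_def.denominator_band)
    a = absorbance(cube.reflectance, floor=floor)
    num = a[:, :, num_idx].mean(axis=2)
    den = a[:, :, den_idx].mean(axis=2)
    if index_def.mode == "difference":
        raw = num - den
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.inf)
    lo, hi = index_def.scale
    values = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    return IndexMap(values=values, index_name=index_def.name)


def compute_all_indices(
    cube: Hypercube,
    index_defs: Mapping[str, BandRatioIndexDef] | None = None,
    floor: float = ABSORBANCE_FLOOR,
) -> dict[str, IndexMap]:
    """Apply :func:`compute_index` for each configured definition (4 by default)."""
    defs = DEFAULT_INDEX_DEFS if index_defs is None else index_defs
    return {name: compute_index(cube, d, floor=floor) for name, d in defs.items()}


def region_mean_index(index_map: IndexMap, mask: np.ndarray) -> float:
    """Arithmetic mean of the index over the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != index_map.values.shape:
        raise ValueError("mask shape does not match index map")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return float(index_map.values[mask].mean())
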