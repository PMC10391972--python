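"""Feather isoscapes: environmental-to-tissue calibration and range masking.

An isoscape is a raster model of an isotope ratio across a landscape.  For
assignment the environmental surfaces must be rescaled to the tissue being
measured: growing-season precipitation δ²H is converted to feather δ²H with
a linear calibration fitted for non-ground-foraging Nearctic–Neotropical
migrants (δ²H_f = 17.57 + 0.95 · δ²H_p), and a plant δ¹³C surface is shifted
by a +2‰ diet–tissue discrimination (plants → herbivorous insects →
feathers).  Both coefficients are parameters so other taxa's transfer
functions can be swapped in.

Per-cell predictive standard deviations are rarely published with an
isoscape; an :class:`Isoscape` therefore carries either a scalar SD applied
everywhere or a full SD raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import GeometryError, RasterGrid

__all__ = [
    "Isoscape",
    "H_CALIBRATION_SLOPE",
    "H_CALIBRATION_INTERCEPT",
    "C_DISCRIMINATION_OFFSET",
    "DEFAULT_SD_H",
    "DEFAULT_SD_C",
    "calibrate_h_isoscape",
    "plant_to_feather_c",
    "apply_range_mask",
]

#: Precipitation→feather δ²H transfer for aerially foraging migrant birds.
H_CALIBRATION_SLOPE = 0.95
H_CALIBRATION_INTERCEPT = 17.57  # ‰

#: Plant→feather δ¹³C trophic discrimination (plants to insectivore keratin).
C_DISCRIMINATION_OFFSET = 2.0  # ‰

#: Default assignment SDs for synthetic runs (‰).
DEFAULT_SD_H = 12.0
DEFAULT_SD_C = 1.5


@dataclass
class Isoscape:
    """Mean (and SD) surface for one isotope.

    ``sd`` is either a positive scalar (‰, applied at every valid cell) or a
    :class:`RasterGrid` sharing the mean's geometry.
    """

    mean: RasterGrid
    sd: float | RasterGrid
    isotope: str  # "d2h" or "d13c"

    def __post_init__(self) -> None:
        if self.isotope not in ("d2h", "d13c"):
            raise ValueError(f"isotope must be 'd2h' or 'd13c', got {self.isotope!r}")
        if isinstance(self.sd, RasterGrid):
            self.mean.require_same_geometry(self.sd, check_mask=True)
            if not np.all(self.sd.values[self.sd.mask] > 0):
                raise ValueError("sd raster must be > 0 on valid cells")
        elif not self.sd > 0:
            raise ValueError("scalar sd must be > 0")

    def sd_array(self) -> np.ndarray:
        """SD as a full array over the grid (NaN on invalid cells)."""
        if isinstance(self.sd, RasterGrid):
            return self.sd.values
        out = np.full(self.mean.shape, np.nan)
        out[self.mean.mask] = float(self.sd)
        return out


def calibrate_h_isoscape(
    precip: RasterGrid,
    slope: float = H_CALIBRATION_SLOPE,
    intercept: float = H_CALIBRATION_INTERCEPT,
    sd: float | RasterGrid = DEFAULT_SD_H,
) -> Isoscape:
    """Convert a precipitation δ²H surface to a feather δ²H isoscape.

    Each valid cell becomes ``intercept + slope * d2h_p``; the validity mask
    is preserved unchanged.
    """
    mean = precip.copy_with(values=intercept + slope * precip.values)
    return Isoscape(mean=mean, sd=sd, isotope="d2h")


def plant_to_feather_c(
    plant: RasterGrid,
    offset: float = C_DISCRIMINATION_OFFSET,
    sd: float | RasterGrid = DEFAULT_SD_C,
) -> Isoscape:
    """Shift a plant δ¹³C surface by the diet–tissue discrimination offset."""
    mean = plant.copy_with(values=plant.values + offset)
    return Isoscape(mean=mean, sd=sd, isotope="d13c")


def apply_range_mask(iso: Isoscape, range_mask: RasterGrid) -> Isoscape:
    """Restrict an isoscape to a species range.

    ``range_mask`` is a raster whose valid cells with nonzero value mark the
    range; the result's validity mask is the AND of the isoscape mask and
    the range.  Values are untouched.  Geometry mismatch raises
    :class:`~isomigrate.raster.GeometryError`.
    """
    if not iso.mean.same_geometry(range_mask):
        raise GeometryError("range mask geometry does not match isoscape")
    in_range = range_mask.mask & (np.nan_to_num(range_mask.values, nan=0.0) != 0)
    new_mask = iso.mean.mask & in_range
    mean = iso.mean.copy_with(mask=new_mask)
    sd = iso.sd
    if isinstance(sd, RasterGrid):
        sd = sd.copy_with(mask=new_mask)
    return Isoscape(mean=mean, sd=sd, isotope=iso.isotope)
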