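"""Infrared-thermography summarization for whole-plant temperature studies.

A thermal scene is a 2-D surface-temperature raster (degrees C) together with a
boolean plant mask.  Plant temperature (PT) is the area-average of the raster
over the mask, soil temperature (ST) the average over the mask complement (or
an explicit soil sub-mask, to exclude rock or sky pixels).  Thermal decoupling
is TD = PT - AT, negative when the plant is cooler than the surrounding air.
Vapor pressure deficit (VPD) is derived from air temperature and relative
humidity through the Tetens saturation vapor pressure formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ThermalScene",
    "PlantObservation",
    "plant_temperature",
    "soil_temperature",
    "region_statistics",
    "thermal_decoupling",
    "saturation_vapor_pressure",
    "vpd",
    "read_grid",
    "scene_to_observation",
    "observations_to_frame",
    "OBSERVATION_COLUMNS",
]

#: Column order used when plant observations are written to CSV.
OBSERVATION_COLUMNS = [
    "individual", "species", "growth_form", "date", "period",
    "PT", "ST", "AT", "RH", "WS", "PAR", "TD", "VPD",
]

# Tetens constants (kPa, dimensionless, degrees C); standard agrometeorology
# convention for saturation vapor pressure over water.
_TETENS_A = 0.6108
_TETENS_B = 17.27
_TETENS_C = 237.3


@dataclass
class ThermalScene:
    """A temperature raster with its plant region mask.

    Parameters
    ----------
    grid : ndarray
        2-D array of surface temperatures in degrees C.
    plant_mask : ndarray
        Boolean array of the same shape; True marks plant pixels.
    soil_mask : ndarray, optional
        Explicit soil region.  When absent the complement of ``plant_mask``
        is used as the soil region.
    metadata : dict
        Free-form scene annotations (species, timestamp, period P1/P2/P3...).
    """

    grid: np.ndarray
    plant_mask: np.ndarray
    soil_mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.plant_mask = np.asarray(self.plant_mask, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("grid must be a 2-D raster")
        if self.grid.shape != self.plant_mask.shape:
            raise ValueError(
                f"grid shape {self.grid.shape} != mask shape {self.plant_mask.shape}"
            )
        if not self.plant_mask.any():
            raise ValueError("plant_mask has no True pixel")
        if not np.isfinite(self.grid).all():
            raise ValueError("grid contains non-finite temperatures")
        if self.soil_mask is not None:
            self.soil_mask = np.asarray(self.soil_mask, dtype=bool)
            if self.soil_mask.shape != self.grid.shape:
                raise ValueError("soil_mask shape mismatch")
            if not self.soil_mask.any():
                raise ValueError("soil_mask has no True pixel")


@dataclass
class PlantObservation:
    """One plant at one measurement period, with microclimate context.

    TD (K) is always PT - AT; VPD (kPa) always derives from AT and RH.  Both
    are computed in :func:`scene_to_observation` rather than trusted from
    input, so the identity holds to numerical precision.
    """

    individual: str
    species: str
    growth_form: str  # "rosette" | "dwarf shrub"
    date: str
    period: str  # P1 | P2 | P3
    PT: float  # plant surface temperature, degrees C
    ST: float  # soil surface temperature, degrees C
    AT: float  # air temperature at plant height, degrees C
    RH: float  # relative humidity, percent
    WS: float  # wind speed, km/h
    PAR: float  # photosynthetically active radiation, umol m-2 s-1
    TD: float = float("nan")  # thermal decoupling PT - AT, K
    VPD: float = float("nan")  # vapor pressure deficit, kPa

    def __post_init__(self) -> None:
        if not 0.0 <= self.RH <= 100.0:
            raise ValueError(f"RH={self.RH} outside [0, 100] %")
        if self.WS < 0:
            raise ValueError("wind speed must be >= 0")
        if self.PAR < 0:
            raise ValueError("PAR must be >= 0")
        self.TD = thermal_decoupling(self.PT, self.AT)
        self.VPD = vpd(self.AT, self.RH)


def plant_temperature(scene: ThermalScene) -> float:
    """Mean surface temperature (degrees C) over the plant mask."""
    return float(scene.grid[scene.plant_mask].mean())


def soil_temperature(scene: ThermalScene) -> float:
    """Mean surface temperature (degrees C) over the soil region.

    The soil region is ``scene.soil_mask`` when provided, otherwise the
    complement of the plant mask.  Raises ``ValueError`` when the plant mask
    covers the whole grid and no explicit soil mask exists.
    """
    if scene.soil_mask is not None:
        region = scene.soil_mask
    else:
        region = ~scene.plant_mask
        if not region.any():
            raise ValueError("plant mask covers the whole grid; no soil pixels")
    return float(scene.grid[region].mean())


def region_statistics(scene: ThermalScene) -> dict[str, float]:
    """Secondary region statistics (min/max/median) over the plant mask."""
    vals = scene.grid[scene.plant_mask]
    return {
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "median": float(np.median(vals)),
        "n_pixels": int(vals.size),
    }


def thermal_decoupling(pt: float, at: float) -> float:
    """Thermal decoupling TD = PT - AT in K (negative: plant cooler than air)."""
    if not (np.isfinite(pt) and np.isfinite(at)):
        raise ValueError("PT and AT must be finite")
    return float(pt - at)


def saturation_vapor_pressure(t_air: float) -> float:
    """Tetens saturation vapor pressure (kPa) at air temperature ``t_air`` degrees C."""
    t = np.asarray(t_air, dtype=float)
    return _TETENS_A * np.exp(_TETENS_B * t / (t + _TETENS_C))


def vpd(at: float, rh: float) -> float:
    """Vapor pressure deficit in kPa from air temperature (degrees C) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise ValueError("RH must lie in [0, 100] %")
    out = saturation_vapor_pressure(at) * (1.0 - rh_arr / 100.0)
    return float(out) if np.isscalar(rh) or np.ndim(rh) == 0 else out


def read_grid(path: str | Path) -> np.ndarray:
    """Read a 2-D grid from a plain-text raster (.csv grid or .pgm).

    CSV grids are comma-separated rows of numbers; PGM images are read through
    Pillow (plain or binary, lossless integer grids).  Mask files use the same
    formats with nonzero meaning True.
    """
    path = Path(path)
    if path.suffix.lower() == ".pgm":
        from PIL import Image

        return np.asarray(Image.open(path), dtype=float)
    return np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)


def scene_to_observation(
    scene: ThermalScene,
    microclimate: Mapping[str, float],
    **annotations: str,
) -> PlantObservation:
    """Summarize a scene into one :class:`PlantObservation` row.

    ``microclimate`` must provide AT, RH, WS and PAR measured at plant height
    simultaneously with the infrared capture.  TD and VPD are derived here.
    """
    meta = {**scene.metadata, **annotations}
    return PlantObservation(
        individual=str(meta.get("individual", "")),
        species=str(meta.get("species", "")),
        growth_form=str(meta.get("growth_form", "")),
        date=str(meta.get("date", "")),
        period=str(meta.get("period", "")),
        PT=plant_temperature(scene),
        ST=soil_temperature(scene),
        AT=float(microclimate["AT"]),
        RH=float(microclimate["RH"]),
        WS=float(microclimate["WS"]),
        PAR=float(microclimate["PAR"]),
    )


def observations_to_frame(observations: list[PlantObservation]) -> pd.DataFrame:
    """Stack observations into a DataFrame with the documented column order."""
    rows = [{c: getattr(o, c) for c in OBSERVATION_COLUMNS} for o in observations]
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
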