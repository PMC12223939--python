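"""Analysis grid definition.

The pipeline works on a regular lon/lat grid (default 0.1° resolution,
matching regional ocean-model output). Cells are identified by integer
(lat_idx, lon_idx) pairs; coordinates attached to arrays are cell centers,
and point-in-cell membership uses the half-open convention
[edge, edge + resolution): a point exactly on a cell's upper edge belongs
to the next cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GridConfigError(ValueError):
    """Domain extent is not an integer multiple of the resolution."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with cell-center registration.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Domain edges in degrees. Each extent must be an integer multiple
        of ``resolution``.
    resolution : float
        Cell size in degrees (default 0.1).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.1

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridConfigError("resolution must be positive")
        for lo, hi, name in (
            (self.lon_min, self.lon_max, "lon"),
            (self.lat_min, self.lat_max, "lat"),
        ):
            span = hi - lo
            if span <= 0:
                raise GridConfigError(f"{name} extent must be positive")
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise GridConfigError(
                    f"{name} extent {span} is not an integer multiple of "
                    f"resolution {self.resolution}"
                )

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes (west to east)."""
        return self.lon_min + self.resolution * (np.arange(self.n_lon) + 0.5)

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes (south to north)."""
        return self.lat_min + self.resolution * (np.arange(self.n_lat) + 0.5)

    def cell_of(self, lon, lat):
        """Map points to (lat_idx, lon_idx) by the half-open convention.

        Raises
        ------
        ValueError
            If any point falls outside the grid, listing the offenders.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # floor of (x - edge)/res implements [edge, edge+res)
        jx = np.floor((lon - self.lon_min) / self.resolution + 1e-12).astype(int)
        iy = np.floor((lat - self.lat_min) / self.resolution + 1e-12).astype(int)
        bad = (jx < 0) | (jx >= self.n_lon) | (iy < 0) | (iy >= self.n_lat)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))[:20]
            pts = list(
                zip(np.atleast_1d(lon)[idx].tolist(), np.atleast_1d(lat)[idx].tolist())
            )
            raise ValueError(f"points outside grid bounds (first offenders): {pts}")
        return iy, jx

    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)
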