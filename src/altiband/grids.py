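"""Elevation/climate grids and checklist tables, with plain-text IO.

The grid container holds a single-band integer elevation raster (metres)
plus optionally co-registered mean-annual-temperature (MAT, degC) and
mean-annual-precipitation (MAP, mm) layers on the same cell lattice.
Grids round-trip through the ESRI ASCII grid dialect; checklists are CSV
tables with one row per species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHECKLIST_COLUMNS = ["species", "genus", "family", "lifeform", "elev_min", "elev_max"]
LIFEFORMS = ("tree", "shrub", "herb")


@dataclass
class ElevationGrid:
    """A fixed-cell-area elevation raster with optional climate layers.

    Parameters
    ----------
    elevation
        2-D integer array of cell elevations in metres.
    cell_area
        Planimetric area of one cell in m**2 (900 for a 30 m DEM).
    mat, map_
        Optional climate layers co-registered with ``elevation``
        (mean annual temperature in degC, mean annual precipitation in mm).
    """

    elevation: np.ndarray
    cell_area: float = 900.0
    mat: np.ndarray | None = field(default=None)
    map_: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation)
        if self.elevation.ndim != 2 or self.elevation.size == 0:
            raise ValueError("elevation must be a non-empty 2-D array")
        if not np.isfinite(self.elevation).all():
            raise ValueError("elevation contains non-finite values")
        for name in ("mat", "map_"):
            layer = getattr(self, name)
            if layer is not None:
                layer = np.asarray(layer, dtype=float)
                if layer.shape != self.elevation.shape:
                    raise ValueError(f"{name} layer shape {layer.shape} != elevation {self.elevation.shape}")
                setattr(self, name, layer)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_cells(self) -> int:
        return self.elevation.size

    def elevations_flat(self) -> np.ndarray:
        """Cell elevations in raster row-major order (the jitter order)."""
        return self.elevation.ravel(order="C")

    def has_climate(self) -> bool:
        return self.mat is not None and self.map_ is not None


def write_ascii_grid(path, values: np.ndarray, cellsize: float = 30.0, nodata: float = -9999) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc)."""
    values = np.asarray(values)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (values, cellsize). NODATA -> NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter", "yllcenter",
            "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    body = " ".join(lines[i:])
    values = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return values, header.get("cellsize", 1.0)


def write_checklist(path, checklist: pd.DataFrame) -> None:
    validate_checklist(checklist)
    checklist.loc[:, CHECKLIST_COLUMNS].to_csv(path, index=False)


def read_checklist(path) -> pd.DataFrame:
    checklist = pd.read_csv(path)
    validate_checklist(checklist)
    return checklist


def validate_checklist(checklist: pd.DataFrame) -> pd.DataFrame:
    """Check the checklist contract: columns, ranges, life forms, nesting.

    Raises ``ValueError`` on a malformed table, including a genus mapped to
    more than one family (taxonomic nesting must be consistent).
    """
    missing = [c for c in CHECKLIST_COLUMNS if c not in checklist.columns]
    if missing:
        raise ValueError(f"checklist missing columns: {missing}")
    if len(checklist) == 0:
        return checklist
    bad_lf = set(checklist["lifeform"].unique()) - set(LIFEFORMS)
    if bad_lf:
        raise ValueError(f"unknown life forms: {sorted(bad_lf)}")
    if (checklist["elev_min"] > checklist["elev_max"]).any():
        bad = checklist.loc[checklist["elev_min"] > checklist["elev_max"], "species"].tolist()
        raise ValueError(f"elev_min > elev_max for species: {bad[:5]}")
    fam_per_genus = checklist.groupby("genus")["family"].nunique()
    if (fam_per_genus > 1).any():
        bad = fam_per_genus[fam_per_genus > 1].index.tolist()
        raise ValueError(f"genus assigned to multiple families: {bad[:5]}")
    return checklist
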