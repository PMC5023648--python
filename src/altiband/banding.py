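"""Altitudinal band schemes: equal-elevation and equal-area.

Bands use half-open intervals [lower, upper) with the topmost band closed,
so every in-domain elevation maps to exactly one band. Equal-area bands
are built by jittering the integer DEM elevations with independent
U(-0.5, +0.5) draws (one per cell in raster row-major order), sorting,
and splitting the ranked cells into groups whose sizes differ by at most
one; band boundaries sit midway between the jittered values that straddle
each split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ElevationGrid

EQUAL_ELEVATION = "equal_elevation"
EQUAL_AREA = "equal_area"


@dataclass
class BandScheme:
    """An ordered set of altitudinal bands tiling [domain_min, domain_max].

    ``bands`` is a DataFrame with one row per band, columns
    ``index`` (1-based), ``lower``, ``upper``, ``mid``, ``width_m``,
    ``cell_count``, ``area_km2``, ``mat_mean``, ``map_mean``.
    """

    kind: str
    bands: pd.DataFrame
    domain_min: float
    domain_max: float
    n_outside: int = 0
    cell_assignment: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def lowers(self) -> np.ndarray:
        return self.bands["lower"].to_numpy()

    @property
    def uppers(self) -> np.ndarray:
        return self.bands["upper"].to_numpy()

    @property
    def mids(self) -> np.ndarray:
        return self.bands["mid"].to_numpy()

    def assign_cells(self, elevations: np.ndarray) -> np.ndarray:
        """Map elevations to 0-based band indices; -1 for out-of-domain."""
        elev = np.asarray(elevations, dtype=float)
        edges = np.append(self.lowers, self.uppers[-1])
        idx = np.searchsorted(edges, elev, side="right") - 1
        idx[elev == self.domain_max] = self.n_bands - 1  # top band closed
        idx[(elev < self.domain_min) | (elev > self.domain_max)] = -1
        return idx

    def to_csv(self, path) -> None:
        out = self.bands.copy()
        out.insert(1, "kind", self.kind)
        out.to_csv(path, index=False)


def _bands_frame(lowers, uppers, counts=None, cell_area=None) -> pd.DataFrame:
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    n = len(lowers)
    frame = pd.DataFrame(
        {
            "index": np.arange(1, n + 1),
            "lower": lowers,
            "upper": uppers,
            "mid": (lowers + uppers) / 2.0,
            "width_m": uppers - lowers,
            "cell_count": 0 if counts is None else np.asarray(counts, dtype=int),
            "area_km2": np.nan,
            "mat_mean": np.nan,
            "map_mean": np.nan,
        }
    )
    if counts is not None and cell_area is not None:
        frame["area_km2"] = frame["cell_count"] * cell_area / 1e6
    return frame


def make_equal_elevation_bands(domain_min: float, domain_max: float, width: float) -> BandScheme:
    """Tile [domain_min, domain_max] with bands of fixed elevational width.

    The span must be an integer multiple of ``width``; a non-divisible
    span raises rather than silently creating a partial top band.
    """
    if domain_max <= domain_min:
        raise ValueError("domain_max must exceed domain_min")
    if width <= 0:
        raise ValueError("width must be positive")
    ratio = (domain_max - domain_min) / width
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ValueError(
            f"span {domain_max - domain_min} m is not a multiple of width {width} m; "
            "adjust the domain so bands tile it exactly"
        )
    lowers = domain_min + width * np.arange(n)
    uppers = lowers + width
    return BandScheme(EQUAL_ELEVATION, _bands_frame(lowers, uppers), domain_min, domain_max)


def assign_band_areas(scheme: BandScheme, grid: ElevationGrid) -> BandScheme:
    """Populate per-band cell counts and areas from a DEM.

    Band area = cell_area x cells-in-band (planimetric). Cells outside
    the scheme's domain are excluded and counted in ``n_outside``.
    """
    if grid.n_cells == 0:
        raise ValueError("empty grid")
    elev = grid.elevations_flat()
    idx = scheme.assign_cells(elev)
    outside = int((idx < 0).sum())
    counts = np.bincount(idx[idx >= 0], minlength=scheme.n_bands)
    bands = scheme.bands.copy()
    bands["cell_count"] = counts
    bands["area_km2"] = counts * grid.cell_area / 1e6
    return BandScheme(scheme.kind, bands, scheme.domain_min, scheme.domain_max,
                      n_outside=outside, cell_assignment=idx)


def jitter_elevations(elevations: np.ndarray, seed: int) -> np.ndarray:
    """Integer DEM values plus one independent U(-0.5, +0.5) draw per cell.

    Draws are taken in raster row-major order from ``seed`` so band
    boundaries are reproducible across runs.
    """
    rng = np.random.default_rng(seed)
    return np.asarray(elevations, dtype=float) + rng.uniform(-0.5, 0.5, size=len(elevations))


def make_equal_area_bands(grid: ElevationGrid, n_bands: int, seed: int = 0,
                          domain: tuple[float, float] | None = None) -> BandScheme:
    """Split the DEM cells into ``n_bands`` bands of (near-)equal cell count.

    Jittered elevations are ranked and cut into contiguous groups whose
    sizes differ by at most one (the first ``n_cells mod n_bands`` groups
    take the extra cell). Interior boundaries are midpoints between the
    jittered values straddling each cut; the outer boundaries clamp to
    the domain. Band widths are therefore unequal: narrow where the
    hypsographic density is high, wide in the sparse tails.
    """
    if domain is None:
        domain = (float(grid.elevation.min()), float(grid.elevation.max()))
    lo, hi = domain
    elev = grid.elevations_flat()
    in_dom = (elev >= lo) & (elev <= hi)
    n_cells = int(in_dom.sum())
    if n_bands < 1 or n_bands > n_cells:
        raise ValueError(f"n_bands={n_bands} exceeds in-domain cell count {n_cells}")

    jittered_all = jitter_elevations(elev, seed)
    jittered = jittered_all[in_dom]
    order = np.argsort(jittered, kind="stable")
    sorted_j = jittered[order]

    base, rem = divmod(n_cells, n_bands)
    sizes = np.full(n_bands, base, dtype=int)
    sizes[:rem] += 1
    cuts = np.cumsum(sizes)[:-1]

    inner = (sorted_j[cuts - 1] + sorted_j[cuts]) / 2.0
    lowers = np.concatenate(([lo], inner))
    uppers = np.concatenate((inner, [hi]))

    bands = _bands_frame(lowers, uppers, counts=sizes, cell_area=grid.cell_area)
    # per-cell band index from the ranked split (consistent with boundaries)
    band_of_rank = np.repeat(np.arange(n_bands), sizes)
    assignment = np.full(len(elev), -1, dtype=int)
    in_idx = np.flatnonzero(in_dom)
    assignment[in_idx[order]] = band_of_rank
    return BandScheme(EQUAL_AREA, bands, lo, hi,
                      n_outside=int((~in_dom).sum()), cell_assignment=assignment)


def summarize_band_climate(scheme: BandScheme, grid: ElevationGrid) -> BandScheme:
    """Attach per-band arithmetic means of MAT and MAP.

    Uses the scheme's stored cell assignment when available (the ranked
    split for equal-area schemes), otherwise assigns cells by interval.
    Empty bands get NaN means.
    """
    if not grid.has_climate():
        raise ValueError("grid has no climate layers; run generate_climate or load them")
    idx = scheme.cell_assignment
    if idx is None or len(idx) != grid.n_cells:
        idx = scheme.assign_cells(grid.elevations_flat())
    bands = scheme.bands.copy()
    for col, layer in (("mat_mean", grid.mat), ("map_mean", grid.map_)):
        vals = layer.ravel(order="C")
        keep = idx >= 0
        sums = np.bincount(idx[keep], weights=vals[keep], minlength=scheme.n_bands)
        counts = np.bincount(idx[keep], minlength=scheme.n_bands)
        with np.errstate(invalid="ignore"):
            bands[col] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if (bands["cell_count"] == 0).all():
        bands["cell_count"] = np.bincount(idx[idx >= 0], minlength=scheme.n_bands)
        bands["area_km2"] = bands["cell_count"] * grid.cell_area / 1e6
    return BandScheme(scheme.kind, bands, scheme.domain_min, scheme.domain_max,
                      n_outside=scheme.n_outside, cell_assignment=idx)
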