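"""Synthetic mountains and floras for testing the banding pipeline.

The generator emulates the statistical structure the analysis relies on,
not terrain: a hypsography (cell-count-per-band profile) that is
hump-shaped in elevation, MAT decreasing linearly with elevation, MAP
following a piecewise-linear rise-fall-rise profile, and a checklist of
species with nested genus/family labels, tree/shrub/herb life forms, and
elevational range sizes drawn from a three-group mixture
(<150 m, 150-500 m, >500 m).

Defaults mirror a high subtropical mountain: a 1350-5050 m domain, the
hypsographic mode near 2700 m, 900 m**2 cells, a 2028-species flora with
group proportions 830/554/644 and 717 single-record species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import CHECKLIST_COLUMNS, ElevationGrid

#: group proportions of a 2028-species flora split 830 / 554 / 644
DEFAULT_GROUP_PROPORTIONS = (830 / 2028, 554 / 2028, 644 / 2028)
#: tree / shrub / herb proportions for 290 / 392 / 1346 species
DEFAULT_LIFEFORM_PROPORTIONS = (290 / 2028, 392 / 2028, 1346 / 2028)
#: fraction of species known from a single elevation record (717 of 2028)
DEFAULT_SINGLE_RECORD_FRACTION = 717 / 2028


def _check_proportions(name: str, props) -> np.ndarray:
    props = np.asarray(props, dtype=float)
    if props.shape != (3,) or (props < 0).any() or (props > 1).any():
        raise ValueError(f"{name} must be three fractions in [0, 1]")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {props.sum()!r})")
    return props


@dataclass
class MountainParams:
    """Parameters of the synthetic elevation/climate grids.

    ``hump_peak_elev`` sets the elevation of maximum band area; the
    hypsography is a mixture of two truncated normals (a sharp component
    at the peak plus a broad high-elevation shoulder) so the band-area
    profile is unimodal with a heavy upper tail. ``lapse_rate`` is in
    degC per metre and must be positive (MAT decreases upward).
    ``map_profile`` lists (elevation_m, precip_mm) breakpoints of a
    piecewise-linear MAP curve.
    """

    domain_min_elev: float = 1350.0
    domain_max_elev: float = 5050.0
    grid_shape: tuple[int, int] = (120, 120)
    cell_area: float = 900.0
    hump_peak_elev: float = 2700.0
    mat_at_base: float = 12.0
    lapse_rate: float = 0.006
    map_profile: tuple[tuple[float, float], ...] = (
        (1350.0, 950.0),
        (1900.0, 1200.0),
        (4200.0, 912.0),
        (5050.0, 1050.0),
    )
    climate_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_min_elev >= self.domain_max_elev:
            raise ValueError("domain_min_elev must be < domain_max_elev")
        if not (self.domain_min_elev < self.hump_peak_elev < self.domain_max_elev):
            raise ValueError("hump_peak_elev must lie strictly inside the domain")
        if self.lapse_rate < 0:
            raise ValueError("lapse_rate must be >= 0 (MAT decreases upward)")
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape must be positive")
        elevs = [e for e, _ in self.map_profile]
        if sorted(elevs) != list(elevs):
            raise ValueError("map_profile breakpoints must be sorted by elevation")

    @property
    def span(self) -> float:
        return self.domain_max_elev - self.domain_min_elev


@dataclass
class ChecklistParams:
    """Parameters of the synthetic species checklist."""

    n_species: int = 2028
    group_proportions: tuple[float, float, float] = DEFAULT_GROUP_PROPORTIONS
    lifeform_proportions: tuple[float, float, float] = DEFAULT_LIFEFORM_PROPORTIONS
    single_record_fraction: float = DEFAULT_SINGLE_RECORD_FRACTION
    genera_per_family: float = 625 / 136
    species_per_genus: float = 2028 / 625
    richness_profile: object = None  # callable elevation -> weight; None = unimodal default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise ValueError("n_species must be >= 0")
        _check_proportions("group_proportions", self.group_proportions)
        _check_proportions("lifeform_proportions", self.lifeform_proportions)
        if not 0 <= self.single_record_fraction <= 1:
            raise ValueError("single_record_fraction must be in [0, 1]")
        if self.genera_per_family <= 0 or self.species_per_genus <= 0:
            raise ValueError("taxonomic means must be positive")


def generate_elevation_grid(params: MountainParams) -> ElevationGrid:
    """Sample a DEM whose hypsography is hump-shaped with mode at the peak.

    Cell elevations are drawn from a two-component mixture of truncated
    normals on [domain_min, domain_max] — 70 % mass in a tight component
    centred on ``hump_peak_elev`` and 30 % in a broad component displaced
    upslope — then rounded to integer metres (the DEM dialect the
    equal-area jitter rule assumes) and clipped into the domain.
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.domain_min_elev, params.domain_max_elev
    n = params.grid_shape[0] * params.grid_shape[1]

    sd1 = max(params.span / 8.0, 1.0)
    mu2 = min(params.hump_peak_elev + params.span / 3.0, hi)
    sd2 = max(params.span / 3.0, 1.0)

    def _cdf(x, mu, sd):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.cdf(x, a, b, loc=mu, scale=sd)

    # integer support; mixture CDF evaluated at the half-metre cell edges
    support = np.arange(np.ceil(lo), np.floor(hi) + 1, dtype=int)
    edges = np.append(support - 0.5, support[-1] + 0.5).clip(lo, hi)
    cdf = 0.7 * _cdf(edges, params.hump_peak_elev, sd1) + 0.3 * _cdf(edges, mu2, sd2)
    # stratified inverse-CDF draw: per-metre cell counts deviate from their
    # expectation by at most 1, so the histogram mode is structural, not lucky
    u = (np.arange(n) + rng.random(n)) / n
    elev = support[np.clip(np.searchsorted(cdf, u, side="right") - 1, 0, len(support) - 1)]
    elev = rng.permutation(elev)
    return ElevationGrid(elev.reshape(params.grid_shape), cell_area=params.cell_area)


def generate_climate(grid: ElevationGrid, params: MountainParams) -> ElevationGrid:
    """Attach MAT and MAP layers to an elevation grid.

    MAT(cell) = mat_at_base - lapse_rate * (elev - domain_min) + noise;
    MAP(cell) interpolates ``map_profile`` piecewise-linearly in elevation,
    plus noise. Noise is iid Gaussian with sd ``climate_noise_sd`` (default 0).
    """
    if grid is None or grid.elevation is None:
        raise ValueError("grid with an elevation layer is required")
    rng = np.random.default_rng(params.seed + 1)
    elev = grid.elevation.astype(float)
    mat = params.mat_at_base - params.lapse_rate * (elev - params.domain_min_elev)
    xp = np.array([e for e, _ in params.map_profile])
    fp = np.array([p for _, p in params.map_profile])
    map_ = np.interp(elev, xp, fp)
    if params.climate_noise_sd > 0:
        mat = mat + rng.normal(0.0, params.climate_noise_sd, elev.shape)
        map_ = map_ + rng.normal(0.0, params.climate_noise_sd, elev.shape)
    return ElevationGrid(grid.elevation, cell_area=grid.cell_area, mat=mat, map_=map_)


def _default_profile(domain: tuple[float, float]):
    lo, hi = domain
    mid, sd = (lo + hi) / 2.0, (hi - lo) / 4.0

    def profile(e):
        return np.exp(-0.5 * ((np.asarray(e, dtype=float) - mid) / sd) ** 2)

    return profile


def _sample_profile(rng, profile, lo_arr, hi_arr):
    """Sample one midpoint per species from ``profile`` restricted to [lo, hi]."""
    out = np.empty(len(lo_arr))
    grid = np.linspace(0.0, 1.0, 257)
    for i, (a, b) in enumerate(zip(lo_arr, hi_arr)):
        if b <= a:
            out[i] = a
            continue
        xs = a + grid * (b - a)
        w = np.maximum(np.asarray(profile(xs), dtype=float), 0.0)
        if w.sum() <= 0:
            out[i] = rng.uniform(a, b)
            continue
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        out[i] = np.interp(rng.random(), cdf, xs)
    return out


def _taxonomy(rng, n_species: int, species_per_genus: float, genera_per_family: float):
    """Nested genus/family labels: each genus belongs to exactly one family."""
    n_genera = max(1, int(round(n_species / species_per_genus)))
    n_families = max(1, int(round(n_genera / genera_per_family)))
    genus_of_species = rng.integers(0, n_genera, size=n_species)
    family_of_genus = rng.integers(0, n_families, size=n_genera)
    genera = np.array([f"genus_{g:04d}" for g in range(n_genera)])
    families = np.array([f"family_{f:03d}" for f in range(n_families)])
    return genera[genus_of_species], families[family_of_genus[genus_of_species]]


def generate_checklist(params: ChecklistParams, domain: tuple[float, float]) -> pd.DataFrame:
    """Draw a species checklist with the three-group range-size mixture.

    Range sizes are uniform on [0, 150) for Group I, [150, 500] for
    Group II and (500, span] for Group III; within Group I a fraction of
    species is collapsed to point records (elev_min = elev_max) so the
    realized single-record share matches ``single_record_fraction``.
    Range midpoints follow ``richness_profile`` (default: a Gaussian bump
    at mid-domain) restricted to each range's feasible interval.
    """
    lo, hi = float(domain[0]), float(domain[1])
    span = hi - lo
    if span <= 0:
        raise ValueError("infeasible domain: min >= max")
    n = params.n_species
    if n == 0:
        return pd.DataFrame(columns=CHECKLIST_COLUMNS)
    if span <= 500 and params.group_proportions[2] > 0:
        raise ValueError("domain span too small for Group III ranges (>500 m)")
    if span < 150 and params.group_proportions[1] > 0:
        raise ValueError("domain span too small for Group II ranges (150-500 m)")

    rng = np.random.default_rng(params.seed)
    props = np.asarray(params.group_proportions, dtype=float)
    group = rng.choice(3, size=n, p=props)

    r = np.empty(n)
    g0, g1, g2 = group == 0, group == 1, group == 2
    r[g0] = rng.uniform(0.0, min(150.0, span), size=int(g0.sum()))
    r[g1] = rng.uniform(150.0, min(500.0, span), size=int(g1.sum()))
    r[g2] = rng.uniform(np.nextafter(500.0, np.inf), span, size=int(g2.sum()))
    # point records live inside Group I so group proportions are preserved
    if props[0] > 0 and params.single_record_fraction > 0:
        f_within = min(1.0, params.single_record_fraction / props[0])
        collapse = g0 & (rng.random(n) < f_within)
        r[collapse] = 0.0

    profile = params.richness_profile or _default_profile((lo, hi))
    mid = _sample_profile(rng, profile, lo + r / 2.0, hi - r / 2.0)
    elev_min = np.clip(mid - r / 2.0, lo, hi)
    elev_max = np.clip(mid + r / 2.0, lo, hi)

    lifeform = rng.choice(np.array(["tree", "shrub", "herb"]), size=n,
                          p=np.asarray(params.lifeform_proportions, dtype=float))
    genus, family = _taxonomy(rng, n, params.species_per_genus, params.genera_per_family)
    return pd.DataFrame(
        {
            "species": [f"sp_{i:05d}" for i in range(n)],
            "genus": genus,
            "family": family,
            "lifeform": lifeform,
            "elev_min": elev_min,
            "elev_max": elev_max,
        }
    )
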