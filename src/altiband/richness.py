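"""Interpolated presence and per-band taxon richness counting.

A species is taken to occupy every elevation between its recorded
minimum and maximum (range interpolation), so it is counted in every
band whose interval intersects the closed range [elev_min, elev_max] —
including a band touched only at its lower edge. Nine richness
variables are tallied per band: species / genus / family richness
(S, G, F), life-form species richness (TS, SS, HS) and range-size-group
species richness (IS, IIS, IIIS for ranges <150 m, 150-500 m, >500 m).

The same counting runs unchanged on an equal-area scheme — that re-count
is the "equal-area" area-correction (method 2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .banding import BandScheme
from .grids import validate_checklist

RICHNESS_COLUMNS = ["S", "G", "F", "TS", "SS", "HS", "IS", "IIS", "IIIS"]

#: range-size group thresholds in metres: <150 -> I, 150-500 -> II, >500 -> III
GROUP_THRESHOLDS = (150.0, 500.0)


def range_size_group(elev_min: float, elev_max: float,
                     thresholds: tuple[float, float] = GROUP_THRESHOLDS) -> str:
    """Classify a species' elevational range size into Group I, II or III.

    Boundary values fall in Group II: a range of exactly 150 m or exactly
    500 m is "between 150 and 500".
    """
    r = elev_max - elev_min
    if r < 0:
        raise ValueError("elev_min exceeds elev_max")
    lo, hi = thresholds
    if r < lo:
        return "I"
    if r <= hi:
        return "II"
    return "III"


def _presence_matrix(elev_min: np.ndarray, elev_max: np.ndarray, scheme: BandScheme) -> np.ndarray:
    """(n_species, n_bands) boolean presence by closed-range intersection."""
    lowers = scheme.lowers[None, :]
    uppers = scheme.uppers[None, :]
    emin = np.asarray(elev_min, dtype=float)[:, None]
    emax = np.asarray(elev_max, dtype=float)[:, None]
    present = (lowers <= emax) & (emin < uppers)
    # topmost band is closed above
    present[:, -1] |= (emin[:, 0] <= scheme.uppers[-1]) & (emax[:, 0] >= scheme.lowers[-1])
    return present


def interpolate_presence(elev_min: float, elev_max: float, scheme: BandScheme) -> list[int]:
    """Band indices (1-based) intersected by the closed range [elev_min, elev_max].

    The returned indices form a contiguous run. A record outside the
    scheme's domain raises.
    """
    if elev_min > elev_max:
        raise ValueError("elev_min exceeds elev_max")
    if elev_max < scheme.domain_min or elev_min > scheme.domain_max:
        raise ValueError(
            f"range [{elev_min}, {elev_max}] lies outside the domain "
            f"[{scheme.domain_min}, {scheme.domain_max}]"
        )
    row = _presence_matrix(np.array([elev_min]), np.array([elev_max]), scheme)[0]
    return (np.flatnonzero(row) + 1).tolist()


def _check_records(checklist: pd.DataFrame, scheme: BandScheme) -> None:
    dup = checklist[checklist.duplicated("species", keep=False)]
    if len(dup):
        conflicting = dup.groupby("species").filter(
            lambda g: g[["elev_min", "elev_max"]].nunique().max() > 1
        )
        if len(conflicting):
            raise ValueError(
                "duplicate species with conflicting ranges: "
                f"{sorted(conflicting['species'].unique())[:5]}"
            )
    out = checklist[(checklist["elev_max"] < scheme.domain_min)
                    | (checklist["elev_min"] > scheme.domain_max)]
    if len(out):
        raise ValueError(f"species outside the domain: {out['species'].tolist()[:5]}")


def richness_table(checklist: pd.DataFrame, scheme: BandScheme,
                   thresholds: tuple[float, float] = GROUP_THRESHOLDS) -> pd.DataFrame:
    """Count the nine richness variables in every band of a scheme.

    Returns a DataFrame indexed like the scheme's bands (1-based ``band``)
    with integer columns S, G, F, TS, SS, HS, IS, IIS, IIIS. Genus and
    family presence derive from species presence: a genus (family) is
    present wherever at least one of its species is.
    """
    validate_checklist(checklist)
    n_bands = scheme.n_bands
    empty = pd.DataFrame(0, index=pd.RangeIndex(1, n_bands + 1, name="band"),
                         columns=RICHNESS_COLUMNS)
    if len(checklist) == 0:
        return empty
    checklist = checklist.drop_duplicates()
    _check_records(checklist, scheme)

    pres = _presence_matrix(checklist["elev_min"].to_numpy(),
                            checklist["elev_max"].to_numpy(), scheme)
    table = empty.copy()
    table["S"] = pres.sum(axis=0)
    for col, labels in (("G", checklist["genus"]), ("F", checklist["family"])):
        codes, _ = pd.factorize(labels)
        n_taxa = codes.max() + 1
        taxon_pres = np.zeros((n_taxa, n_bands), dtype=bool)
        np.logical_or.at(taxon_pres, codes, pres)
        table[col] = taxon_pres.sum(axis=0)
    lifeform = checklist["lifeform"].to_numpy()
    for col, lf in (("TS", "tree"), ("SS", "shrub"), ("HS", "herb")):
        table[col] = pres[lifeform == lf].sum(axis=0)
    sizes = (checklist["elev_max"] - checklist["elev_min"]).to_numpy()
    groups = np.where(sizes < thresholds[0], "I", np.where(sizes <= thresholds[1], "II", "III"))
    for col, g in (("IS", "I"), ("IIS", "II"), ("IIIS", "III")):
        table[col] = pres[groups == g].sum(axis=0)
    return table


def lifeform_composition(checklist: pd.DataFrame) -> dict[str, float]:
    """Flora composition by life form, in percent of all species.

    Returns percentages for tree, shrub, herb, plus the herbaceous and
    woody (tree + shrub) totals, each rounded to one decimal place.
    """
    validate_checklist(checklist)
    n = len(checklist)
    if n == 0:
        raise ValueError("empty checklist")
    counts = checklist["lifeform"].value_counts()
    pct = {lf: round(float(100.0 * counts.get(lf, 0) / n), 1)
           for lf in ("tree", "shrub", "herb")}
    pct["herbaceous"] = pct["herb"]
    pct["woody"] = round(float(100.0 * (counts.get("tree", 0) + counts.get("shrub", 0)) / n), 1)
    return pct


def single_band_subset(checklist: pd.DataFrame, scheme: BandScheme) -> pd.DataFrame:
    """Species whose interpolated presence covers exactly one band.

    Counting richness of this subset needs no interpolation, which makes
    it the natural probe for interpolation artefacts in the full table.
    """
    validate_checklist(checklist)
    if len(checklist) == 0:
        return checklist
    _check_records(checklist, scheme)
    pres = _presence_matrix(checklist["elev_min"].to_numpy(),
                            checklist["elev_max"].to_numpy(), scheme)
    return checklist[pres.sum(axis=1) == 1]
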