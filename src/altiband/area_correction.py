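"""Species-area relationship fits and power-law area correction.

Three linearised versions of the species-area relationship are fitted by
OLS — untransformed (S ~ A), semi-log (S ~ ln A) and log-log
(ln S ~ ln A) — and compared by small-sample AICc,

    AICc = -2 logLik + 2 K n / (n - K - 1),

with K = 3 (slope, intercept, error variance). The log-log version is
the power law S = c A**z; its slope is the exponent z used to rescale
observed richness to a fixed reference area:

    TRcor1 = 100 * TRobs / A**z.

Bands with zero richness are excluded from all three fits (the same band
subset throughout, so the AICc values are comparable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

VERSIONS = ("untransformed", "semilog", "loglog")

#: parameters counted in AICc for simple linear regression: slope, intercept, sigma^2
K_OLS_SIMPLE = 3


def aicc(loglik: float, n: int, K: int) -> float:
    """Small-sample-corrected Akaike information criterion.

    Undefined (raises) when n <= K + 1, where the correction term blows up.
    """
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n}, K={K} (need n > K + 1)")
    return -2.0 * loglik + 2.0 * K * n / (n - K - 1)


@dataclass
class SpeciesAreaFit:
    """One OLS fit of a species-area version.

    For ``version='loglog'`` the slope is the power-law exponent z and
    the intercept is ln c (natural logs on both axes).
    """

    version: str
    slope: float
    intercept: float
    slope_se: float
    adj_r2: float
    p_value: float
    loglik: float
    aicc: float
    n_used: int
    n_dropped_zero: int = 0
    delta_aicc: float = float("nan")
    co_best: bool = False

    def to_dict(self) -> dict:
        return {
            "version": self.version, "slope": self.slope, "intercept": self.intercept,
            "adj_r2": self.adj_r2, "p_value": self.p_value, "loglik": self.loglik,
            "aicc": self.aicc, "delta_aicc": self.delta_aicc, "n_used": self.n_used,
        }


def fit_species_area(richness, area, version: str) -> SpeciesAreaFit:
    """OLS fit of one species-area version on the positive-richness bands.

    ``richness`` and ``area`` are per-band vectors (area in km**2). The
    Gaussian log-likelihood is evaluated at the ML residual variance so
    AICc (K = 3) is comparable across versions.
    """
    if version not in VERSIONS:
        raise ValueError(f"unknown version {version!r}; expected one of {VERSIONS}")
    richness = np.asarray(richness, dtype=float)
    area = np.asarray(area, dtype=float)
    if richness.shape != area.shape:
        raise ValueError("richness and area must have matching lengths")
    keep = richness > 0
    n_dropped = int((~keep).sum())
    richness, area = richness[keep], area[keep]
    if len(richness) == 0:
        raise ValueError("all bands have zero richness")
    if (area <= 0).any():
        raise ValueError("bands with positive richness must have positive area")
    if len(richness) < 3:
        raise ValueError(f"need >= 3 usable bands, got {len(richness)}")

    x = np.log(area) if version in ("semilog", "loglog") else area
    y = np.log(richness) if version == "loglog" else richness
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SpeciesAreaFit(
        version=version,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        adj_r2=float(res.rsquared_adj),
        p_value=float(res.f_pvalue),
        loglik=float(res.llf),
        # AICc is undefined below n = K + 2; tiny fits still report the OLS part
        aicc=(aicc(float(res.llf), int(res.nobs), K_OLS_SIMPLE)
              if res.nobs > K_OLS_SIMPLE + 1 else float("nan")),
        n_used=int(res.nobs),
        n_dropped_zero=n_dropped,
    )


def select_best_version(fits: list[SpeciesAreaFit]) -> SpeciesAreaFit:
    """Pick the minimum-AICc fit and populate delta-AICc for all.

    Rival fits within 2 AICc units of the best are flagged ``co_best``
    (statistically indistinguishable support). All fits must use the
    same band subset or the comparison is invalid.
    """
    if len({f.n_used for f in fits}) != 1:
        raise ValueError("fits use different band subsets; AICc comparison invalid")
    if any(not np.isfinite(f.aicc) for f in fits):
        raise ValueError("AICc undefined for at least one fit (too few bands)")
    best_aicc = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best_aicc
        f.co_best = 0 < f.delta_aicc < 2
    return min(fits, key=lambda f: f.aicc)


def fit_all_versions(richness, area) -> tuple[SpeciesAreaFit, list[SpeciesAreaFit]]:
    """Fit all three versions and select the best; returns (best, all)."""
    fits = [fit_species_area(richness, area, v) for v in VERSIONS]
    return select_best_version(fits), fits


def correct_method1(richness, area, z: float) -> pd.DataFrame:
    """Power-law area correction: TRcor1 = 100 * TRobs / A**z per band.

    Bands with zero richness get TRcor1 = 0. Returns a DataFrame with
    columns ``trcor1``, ``z_used``, ``area_used``.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    richness = np.asarray(richness, dtype=float)
    area = np.asarray(area, dtype=float)
    if ((richness > 0) & (area <= 0)).any():
        raise ValueError("positive richness in a zero-area band")
    trcor1 = np.zeros_like(richness)
    pos = richness > 0
    trcor1[pos] = 100.0 * richness[pos] / area[pos] ** z
    return pd.DataFrame({"trcor1": trcor1, "z_used": z, "area_used": area})
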