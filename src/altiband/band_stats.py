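"""Spatial statistics on band-level responses.

Bands along the gradient are treated as observations on a single
geographic axis. The battery comprises:

* polynomial OLS (order 1 or 2) with AICc order selection — two models
  within 2 AICc units count as equally supported and the first-order fit
  wins for simplicity;
* Moran's I of model residuals on binary distance-class weights,

      I = (n / S) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,

  with S the number of links, plus permutation-test correlograms;
* a simultaneous autoregressive (SAR) error model
  y = X beta + u, u = lambda W u + eps, fitted by profile maximum
  likelihood over lambda with the log-determinant from the eigenvalues
  of the row-standardised W; pseudo-R^2 is the squared Pearson
  correlation between y and the full SAR prediction (trend + spatial
  signal);
* the method-comparison table ranking area-correction methods by SAR
  pseudo-R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .area_correction import aicc as _aicc


# ---------------------------------------------------------------------------
# spatial weights


@dataclass
class SpatialWeights:
    """Binary neighbour weights with their row-standardised form.

    ``raw`` is the symmetric 0/1 adjacency matrix (zero diagonal); ``S``
    is the total number of links (sum of raw weights). Rows of the
    standardised matrix sum to 1, except isolated rows which stay 0.
    """

    raw: np.ndarray
    positions: np.ndarray | None = None
    standardized: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.diag(raw).any():
            raise ValueError("weights must have a zero diagonal")
        if not np.allclose(raw, raw.T):
            raise ValueError("raw weights must be symmetric")
        self.raw = raw
        rowsum = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.standardized = np.where(rowsum > 0, raw / np.maximum(rowsum, 1e-300), 0.0)

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    @property
    def S(self) -> float:
        return float(self.raw.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of the row-standardised matrix.

        D^-1 A is similar to the symmetric D^-1/2 A D^-1/2, so the
        spectrum is real; isolated rows contribute zeros.
        """
        d = self.raw.sum(axis=1)
        active = d > 0
        eig = np.zeros(self.n)
        if active.any():
            a = self.raw[np.ix_(active, active)]
            dh = 1.0 / np.sqrt(d[active])
            sym = dh[:, None] * a * dh[None, :]
            eig[: active.sum()] = np.linalg.eigvalsh(sym)
        return eig


def distance_band_weights(positions, distance: float, step: float | None = None) -> SpatialWeights:
    """Binary weights linking pairs at a given distance class.

    Pairs are neighbours when their separation lies in
    (distance - step/2, distance + step/2]; ``step`` defaults to
    ``distance`` so the first class is (d/2, 3d/2].
    """
    positions = np.asarray(positions, dtype=float)
    step = distance if step is None else step
    sep = np.abs(positions[:, None] - positions[None, :])
    raw = (sep > distance - step / 2.0) & (sep <= distance + step / 2.0)
    np.fill_diagonal(raw, False)
    return SpatialWeights(raw.astype(float), positions=positions)


def rank_adjacency_weights(n: int) -> SpatialWeights:
    """Chain weights: band i neighbours i-1 and i+1 along the gradient.

    The natural scheme for equal-area bands, whose mid-elevations are
    irregular and would leave wide bands isolated under a fixed metric
    neighbourhood distance.
    """
    raw = np.zeros((n, n))
    idx = np.arange(n - 1)
    raw[idx, idx + 1] = raw[idx + 1, idx] = 1.0
    return SpatialWeights(raw, positions=np.arange(n, dtype=float))


# ---------------------------------------------------------------------------
# Moran's I and correlograms


def morans_i(values, weights: SpatialWeights) -> float:
    """Moran's I on the raw binary weights of one distance class."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if weights.n != len(x):
        raise ValueError("weights size does not match values")
    S = weights.S
    if S == 0:
        raise ValueError("no neighbour pairs at this distance class")
    dev = x - x.mean()
    denom = (dev ** 2).sum()
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    num = dev @ weights.raw @ dev
    return float(len(x) / S * num / denom)


def correlogram(residuals, positions, step: float = 100.0, max_lag: int | None = None,
                n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Moran's I at successive distance classes d = step, 2 step, ...

    Each class links pairs separated by (d - step/2, d + step/2]. The
    p-value is a two-sided permutation test (values shuffled over
    positions, fixed seed). Classes with no pairs are omitted.
    """
    x = np.asarray(residuals, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if max_lag is None:
        max_lag = int(np.floor((positions[-1] - positions[0]) / step))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    rows = []
    for lag in range(1, max_lag + 1):
        w = distance_band_weights(positions, lag * step, step)
        if w.S == 0:
            continue
        i_obs = morans_i(x, w)
        i_perm = np.array([morans_i(p, w) for p in perms])
        center = i_perm.mean()
        p = (np.sum(np.abs(i_perm - center) >= abs(i_obs - center)) + 1) / (n_perm + 1)
        rows.append({"class_m": lag * step, "I": i_obs,
                     "n_pairs": int(w.S / 2), "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# polynomial fits (OLS and SAR error)


@dataclass
class PolynomialModelFit:
    """A first- or second-order polynomial fit of richness on a predictor.

    Coefficients follow the Q/S/C convention: quadratic, slope, constant.
    ``r2`` is the adjusted R^2 for OLS and the pseudo-R^2 (squared
    Pearson correlation of observed and predicted) for SAR. ``lam`` is
    the SAR spatial error coefficient.
    """

    response_name: str
    predictor_name: str
    order: int
    engine: str
    coef_Q: float | None
    coef_S: float
    coef_C: float
    r2: float
    p_value: float
    loglik: float
    aicc: float
    n_used: int
    lam: float | None = None
    lam_se: float | None = None
    trend_r2: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)
    fitted: np.ndarray | None = field(default=None, repr=False)
    selected: bool = False
    delta_aicc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "response": self.response_name, "predictor": self.predictor_name,
            "order": self.order, "engine": self.engine,
            "Q": self.coef_Q, "S": self.coef_S, "C": self.coef_C,
            "r2": self.r2, "p": self.p_value, "aicc": self.aicc,
            "lambda": self.lam, "n": self.n_used, "selected": self.selected,
        }


def _design(x: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(x), x]
    if order == 2:
        cols.append(x ** 2)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("degenerate design: predictor collinear or constant")
    return X


def fit_polynomial(y, x, order: int, response_name: str = "y",
                   predictor_name: str = "x") -> PolynomialModelFit:
    """OLS polynomial fit reporting Q/S/C, adjusted R^2, F-test p and AICc.

    K = order + 2 parameters (coefficients plus error variance).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < order + 2:
        raise ValueError(f"need at least {order + 2} bands for order {order}")
    X = _design(x, order)
    res = sm.OLS(y, X).fit()
    params = res.params
    return PolynomialModelFit(
        response_name=response_name, predictor_name=predictor_name,
        order=order, engine="OLS",
        coef_Q=float(params[2]) if order == 2 else None,
        coef_S=float(params[1]), coef_C=float(params[0]),
        r2=float(res.rsquared_adj), p_value=float(res.f_pvalue),
        loglik=float(res.llf),
        aicc=_aicc(float(res.llf), len(y), order + 2),
        n_used=len(y),
        residuals=np.asarray(res.resid), fitted=np.asarray(res.fittedvalues),
    )


def _sar_profile_loglik(lam: float, y, X, W, eig) -> tuple[float, np.ndarray, float]:
    """Concentrated SAR-error log-likelihood at a given lambda.

    Returns (loglik, beta, sigma2). The spatial filter A = I - lam W is
    applied to both sides; beta and sigma^2 are then the OLS/ML solutions
    on the filtered data, and log|A| = sum log(1 - lam eig_i).
    """
    n = len(y)
    A = np.eye(n) - lam * W
    ys, Xs = A @ y, A @ X
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    e = ys - Xs @ beta
    sigma2 = float(e @ e) / n
    one_minus = 1.0 - lam * eig
    if np.any(one_minus <= 0):
        return -np.inf, beta, sigma2
    logdet = float(np.log(one_minus).sum())
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return ll, beta, sigma2


def fit_sar_error(y, x, order: int, weights: SpatialWeights,
                  response_name: str = "y", predictor_name: str = "x") -> PolynomialModelFit:
    """Maximum-likelihood SAR error model with a polynomial trend.

    lambda is estimated by profiling the concentrated likelihood over
    (-1, 1); with lambda = 0 the estimates reduce to OLS. The full
    prediction yhat = X beta + lambda W (y - X beta) feeds the
    pseudo-R^2; the trend-only pseudo-R^2 is reported alongside.
    Coefficient p-values are asymptotic z-tests.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    X = _design(x, order)
    p = X.shape[1]
    if n < p + 2:
        raise ValueError("too few bands for the SAR fit")
    if weights.n != n:
        raise ValueError("weights size does not match data")
    if weights.S == 0:
        raise ValueError("weights have no links (all bands isolated)")
    W = weights.standardized
    eig = weights.eigenvalues()

    def neg_ll(lam: float) -> float:
        return -_sar_profile_loglik(lam, y, X, W, eig)[0]

    opt = optimize.minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-8})
    if not opt.success or not np.isfinite(opt.fun):
        raise RuntimeError(f"SAR lambda optimisation failed: {opt.message}")
    lam = float(opt.x)
    ll, beta, sigma2 = _sar_profile_loglik(lam, y, X, W, eig)

    # numeric curvature of the profile likelihood -> SE(lambda)
    h = 1e-4
    ll_p = _sar_profile_loglik(min(lam + h, 0.9995), y, X, W, eig)[0]
    ll_m = _sar_profile_loglik(max(lam - h, -0.9995), y, X, W, eig)[0]
    curv = -(ll_p - 2 * ll + ll_m) / h ** 2
    lam_se = float(1.0 / np.sqrt(curv)) if curv > 0 else float("nan")

    trend = X @ beta
    u = y - trend
    fitted = trend + lam * (W @ u)
    innov = u - lam * (W @ u)

    def _pseudo_r2(obs, pred):
        if np.std(pred) == 0 or np.std(obs) == 0:
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)

    A = np.eye(n) - lam * W
    Xs = A @ X
    cov_beta = sigma2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov_beta))
    zstats = beta / se
    # model p-value: likelihood-ratio test against the intercept+spatial null
    ll0 = _sar_profile_loglik(lam, y, X[:, :1], W, eig)[0]
    lr = max(2.0 * (ll - ll0), 0.0)
    p_value = float(stats.chi2.sf(lr, df=p - 1))

    K = p + 2  # trend coefficients + lambda + sigma^2
    return PolynomialModelFit(
        response_name=response_name, predictor_name=predictor_name,
        order=order, engine="SAR",
        coef_Q=float(beta[2]) if order == 2 else None,
        coef_S=float(beta[1]), coef_C=float(beta[0]),
        r2=_pseudo_r2(y, fitted), p_value=p_value,
        loglik=float(ll), aicc=_aicc(float(ll), n, K), n_used=n,
        lam=lam, lam_se=lam_se,
        trend_r2=_pseudo_r2(y, trend),
        residuals=innov, fitted=fitted,
    )


def select_order(fit1: PolynomialModelFit, fit2: PolynomialModelFit) -> PolynomialModelFit:
    """AICc order selection with the parsimony tie-break.

    The higher-order model must beat the first-order model by at least
    2 AICc units; otherwise the first-order fit is selected for
    simplicity.
    """
    a, b = sorted((fit1, fit2), key=lambda f: f.order)
    same = (a.response_name == b.response_name and a.predictor_name == b.predictor_name
            and a.engine == b.engine and a.n_used == b.n_used)
    if not same or {a.order, b.order} != {1, 2}:
        raise ValueError("order selection needs matched order-1 and order-2 fits")
    best = min((a, b), key=lambda f: f.aicc)
    for f in (a, b):
        f.delta_aicc = f.aicc - best.aicc
        f.selected = False
    chosen = best if (best is b and a.aicc - b.aicc >= 2) else a
    chosen.selected = True
    return chosen


def compare_methods(fits: list[PolynomialModelFit]) -> pd.DataFrame:
    """Rank area-correction methods by SAR pseudo-R^2.

    ``fits`` carry response names of the form ``<group>_<kind>`` with
    kind in {obs, cor1, cor2}. Returns a long table (group, predictor,
    richness_kind, r2, order, winner) where ``winner`` marks, per
    group x predictor, whether method 1 or method 2 achieves the larger
    pseudo-R^2 ('method1', 'method2' or 'tie'; blank for obs rows).
    """
    rows = []
    for f in fits:
        group, _, kind = f.response_name.rpartition("_")
        rows.append({"group": group, "predictor": f.predictor_name,
                     "richness_kind": kind, "r2": f.r2, "order": f.order,
                     "lambda": f.lam, "p": f.p_value})
    table = pd.DataFrame(rows)
    winners = []
    for _, row in table.iterrows():
        if row["richness_kind"] not in ("cor1", "cor2"):
            winners.append("")
            continue
        cell = table[(table["group"] == row["group"])
                     & (table["predictor"] == row["predictor"])]
        r1 = cell.loc[cell["richness_kind"] == "cor1", "r2"]
        r2_ = cell.loc[cell["richness_kind"] == "cor2", "r2"]
        if len(r1) == 0 or len(r2_) == 0:
            winners.append("unavailable")
        elif float(r1.iloc[0]) > float(r2_.iloc[0]):
            winners.append("method1")
        elif float(r2_.iloc[0]) > float(r1.iloc[0]):
            winners.append("method2")
        else:
            winners.append("tie")
    table["winner"] = winners
    return table
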