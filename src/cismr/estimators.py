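"""The MR point estimators, written from their closed forms.

All estimators consume harmonized variant pairs (exposure beta/se, outcome
beta/se aligned to one effect allele) and return an :class:`MrResult` holding
the causal estimate per 1 SD of exposure, its standard error, p-value, and the
odds-ratio presentation (exp of the log-odds estimate with a 95% CI).

Estimator conventions:

* Wald ratio — single-instrument ratio with the first-order delta-method se.
* IVW — inverse-variance-weighted combination of per-variant ratios, i.e. a
  weighted regression through the origin, with multiplicative random-effects
  scaling of the se floored at 1 and normal p-values.
* MR-Egger — weighted regression of outcome on exposure betas with intercept
  after orienting all exposure betas positive; the intercept estimates average
  directional pleiotropy. Standard errors scale by the residual dispersion
  (floored at 1); p-values use a t distribution on n - 2 df.
* Weighted median — cumulative-weight midpoint interpolation of sorted ratios;
  se from a parametric bootstrap.
* Simple/weighted mode — argmax of a Gaussian-kernel density over the ratios
  (equal or inverse-variance weights); se from the same bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair

Z_95 = 1.959964  # normal 97.5th percentile, the OR CI multiplier

METHOD_WALD = "wald_ratio"
METHOD_IVW = "ivw"
METHOD_EGGER = "mr_egger"
METHOD_WEIGHTED_MEDIAN = "weighted_median"
METHOD_SIMPLE_MODE = "simple_mode"
METHOD_WEIGHTED_MODE = "weighted_mode"

DEFAULT_N_BOOT = 1000
DEFAULT_SEED = 20231116


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are violated."""


@dataclass
class MrResult:
    """One method's causal estimate for one exposure/outcome pair.

    ``fdr_pvalue``, ``q_*``, ``egger_*`` and ``reliable`` are attached by the
    pipeline/sensitivity layers; they stay None at the estimator level except
    for the MR-Egger intercept fields on the mr_egger row itself.
    """

    exposure: str
    outcome: str
    method: str
    n_snps: int
    beta: float
    se: float
    pvalue: float
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pvalue: Optional[float] = None
    fdr_pvalue: Optional[float] = None
    q_stat: Optional[float] = None
    q_pvalue: Optional[float] = None
    reliable: Optional[bool] = None

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - Z_95 * self.se)
        self.ci_high = math.exp(self.beta + Z_95 * self.se)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with its inverse-variance weight."""

    variant_id: str
    ratio: float
    ratio_se: float
    weight: float


def _arrays(pairs: Sequence[HarmonizedPair]) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    for p in pairs:
        if not p.retained:
            raise EstimationError(f"pair {p.variant_id} has status {p.status}; not estimator input")
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    sx = np.array([p.se_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    sy = np.array([p.se_outcome for p in pairs], dtype=float)
    if np.any(bx == 0):
        raise EstimationError("degenerate instrument: beta_exposure = 0")
    return bx, sx, by, sy


def ratio_estimates(pairs: Sequence[HarmonizedPair]) -> List[RatioEstimate]:
    bx, _, by, sy = _arrays(pairs)
    return [
        RatioEstimate(
            variant_id=p.variant_id,
            ratio=float(b_y / b_x),
            ratio_se=float(s_y / abs(b_x)),
            weight=float(b_x**2 / s_y**2),
        )
        for p, b_x, b_y, s_y in zip(pairs, bx, by, sy)
    ]


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(pair: HarmonizedPair, exposure: str = "", outcome: str = "") -> MrResult:
    """Single-instrument estimate betaY/betaX with se = seY/|betaX|."""
    (bx,), _, (by,), (sy,) = _arrays([pair])
    beta = by / bx
    se = sy / abs(bx)
    return MrResult(exposure, outcome, METHOD_WALD, 1, float(beta), float(se), _normal_p(beta, se))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> Tuple[float, float, float]:
    """Return (beta, fixed-effect se, Cochran's Q)."""
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se0 = float(math.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (by / bx - beta) ** 2))
    return beta, se0, q


def ivw(pairs: Sequence[HarmonizedPair], exposure: str = "", outcome: str = "") -> MrResult:
    """Inverse-variance-weighted estimate with multiplicative random effects."""
    if len(pairs) < 2:
        raise EstimationError("ivw requires at least 2 instruments")
    bx, _, by, sy = _arrays(pairs)
    n = len(pairs)
    beta, se0, q = _ivw_core(bx, by, sy)
    se = se0 * max(1.0, math.sqrt(q / (n - 1)))
    return MrResult(exposure, outcome, METHOD_IVW, n, beta, se, _normal_p(beta, se))


def _egger_fit(pairs: Sequence[HarmonizedPair]):
    """Weighted least squares of betaY on betaX with intercept, betaX oriented >= 0.

    Returns (intercept, slope, se_intercept, se_slope, p_intercept, p_slope, df).
    """
    if len(pairs) < 3:
        raise EstimationError("mr_egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(pairs)
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)
    if np.ptp(bx) == 0:
        raise EstimationError("collinear instruments: no variance in oriented beta_exposure")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = (X * w[:, None]).T @ X
    coef = np.linalg.solve(xtwx, (X * w[:, None]).T @ by)
    resid = by - X @ coef
    n = len(pairs)
    df = n - 2
    sigma2 = float(np.sum(w * resid**2) / df)
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se = np.sqrt(np.diag(cov))
    pvals = [float(2.0 * stats.t.sf(abs(c / s), df)) if s > 0 else (1.0 if c == 0 else 0.0)
             for c, s in zip(coef, se)]
    return float(coef[0]), float(coef[1]), float(se[0]), float(se[1]), pvals[0], pvals[1], df


def mr_egger(pairs: Sequence[HarmonizedPair], exposure: str = "", outcome: str = "") -> MrResult:
    intercept, slope, se_i, se_s, p_i, p_s, _ = _egger_fit(pairs)
    res = MrResult(exposure, outcome, METHOD_EGGER, len(pairs), slope, se_s, p_s)
    res.egger_intercept = intercept
    res.egger_intercept_se = se_i
    res.egger_intercept_pvalue = p_i
    return res


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _bootstrap_se(
    pairs: Sequence[HarmonizedPair],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample both beta vectors from their sampling
    distributions, recompute the estimate, and take the sd across draws."""
    bx, sx, by, sy = _arrays(pairs)
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        for b in range(n_boot):
            bxs = rng.normal(bx, sx)
            bys = rng.normal(by, sy)
            estimates[b] = point_fn(bys / bxs, bxs**2 / sy**2)
    return float(np.std(estimates, ddof=1))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    exposure: str = "",
    outcome: str = "",
) -> MrResult:
    """Weighted-median estimator: interpolate sorted ratios at cumulative weight 0.5."""
    if len(pairs) < 3:
        raise EstimationError("weighted_median requires at least 3 instruments")
    bx, _, by, sy = _arrays(pairs)
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(pairs, lambda r, w: _weighted_median_point(r, w), n_boot, seed)
    return MrResult(exposure, outcome, METHOD_WEIGHTED_MEDIAN, len(pairs), beta, se, _normal_p(beta, se))


def _kde_mode_point(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of the weighted Gaussian-kernel density over a fixed 512-point grid.

    Bandwidth h = factor * 0.9 * min(sd, IQR/1.349) * n^(-1/5), taking the
    minimum over the positive candidates; with no positive spread the common
    ratio itself is returned.
    """
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr_scale = float(q75 - q25) / 1.349
    candidates = [v for v in (sd, iqr_scale) if v > 0]
    if not candidates:
        return float(ratios[0])
    h = bandwidth_factor * 0.9 * min(candidates) * n ** (-0.2)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ (weights / weights.sum())
    return float(grid[np.argmax(dens)])


def mode_estimate(
    pairs: Sequence[HarmonizedPair],
    weighted: bool,
    bandwidth_factor: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = DEFAULT_SEED,
    exposure: str = "",
    outcome: str = "",
) -> MrResult:
    """Mode-based estimator (simple: equal weights; weighted: inverse-variance)."""
    if len(pairs) < 3:
        raise EstimationError("mode_estimate requires at least 3 instruments")
    bx, _, by, sy = _arrays(pairs)
    ratios = by / bx
    ivw_weights = bx**2 / sy**2

    def point(r: np.ndarray, w: np.ndarray) -> float:
        wt = w if weighted else np.ones_like(r)
        return _kde_mode_point(r, wt, bandwidth_factor)

    beta = point(ratios, ivw_weights)
    se = _bootstrap_se(pairs, point, n_boot, seed)
    method = METHOD_WEIGHTED_MODE if weighted else METHOD_SIMPLE_MODE
    return MrResult(exposure, outcome, method, len(pairs), beta, se, _normal_p(beta, se))
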