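"""Heterogeneity and pleiotropy diagnostics for an instrument set.

Cochran's Q measures dispersion of the per-variant ratio estimates around the
IVW estimate (chi-square on n - 1 df under homogeneity); the MR-Egger intercept
estimates average directional pleiotropy (t test on n - 2 df). Both are
reported alongside every MR result and flagged at a configurable alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .estimators import EstimationError, _arrays, _egger_fit, _ivw_core
from .harmonize import HarmonizedPair


@dataclass
class SensitivityResult:
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pvalue: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pvalue: Optional[float] = None

    def heterogeneity_detected(self, alpha: float = 0.05) -> bool:
        return self.q_pvalue is not None and self.q_pvalue < alpha

    def pleiotropy_detected(self, alpha: float = 0.05) -> bool:
        return self.egger_intercept_pvalue is not None and self.egger_intercept_pvalue < alpha


def cochran_q(pairs: Sequence[HarmonizedPair]) -> SensitivityResult:
    """Q = sum_j w_j (ratio_j - beta_IVW)^2 with w_j = betaX_j^2 / seY_j^2."""
    if len(pairs) < 2:
        raise EstimationError("cochran_q requires at least 2 instruments")
    bx, _, by, sy = _arrays(pairs)
    _, _, q = _ivw_core(bx, by, sy)
    df = len(pairs) - 1
    return SensitivityResult(q_stat=q, q_df=df, q_pvalue=float(stats.chi2.sf(q, df)))


def egger_intercept_test(pairs: Sequence[HarmonizedPair]) -> SensitivityResult:
    """Intercept, se and two-sided t p-value from the MR-Egger fit."""
    intercept, _, se_i, _, p_i, _, _ = _egger_fit(pairs)
    return SensitivityResult(
        egger_intercept=intercept,
        egger_intercept_se=se_i,
        egger_intercept_pvalue=p_i,
    )


def diagnostics(pairs: Sequence[HarmonizedPair]) -> SensitivityResult:
    """Combined Q (n >= 2) and Egger-intercept (n >= 3) diagnostics; fields the
    instrument count cannot support stay None."""
    res = SensitivityResult()
    if len(pairs) >= 2:
        q = cochran_q(pairs)
        res.q_stat, res.q_df, res.q_pvalue = q.q_stat, q.q_df, q.q_pvalue
    if len(pairs) >= 3:
        e = egger_intercept_test(pairs)
        res.egger_intercept = e.egger_intercept
        res.egger_intercept_se = e.egger_intercept_se
        res.egger_intercept_pvalue = e.egger_intercept_pvalue
    return res
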