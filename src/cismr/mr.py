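"""Two-sample Mendelian randomization estimators and FDR control.

Estimators operate on allele-harmonized summary statistics.  For a
binary outcome the causal estimate is on the log-odds scale per unit
(typically per SD) of the exposure; odds ratios and 95% intervals are
``exp(estimate ± 1.96·se)``.

Implemented methods
-------------------
wald_ratio
    Single-instrument ratio estimate with a two-term first-order delta
    method SE (accounts for sampling error in the exposure association,
    not only the outcome's — conservative at moderate F).
ivw
    Inverse-variance-weighted average of Wald ratios with first-order
    weights beta_exp^2/se_out^2, equivalent to weighted least squares
    through the origin.  Fixed or multiplicative random effects (SE
    inflated by sqrt(max(1, Q/(k-1)))).
egger
    Weighted regression with an intercept capturing average directional
    pleiotropy, after orienting all exposure effects positive.
weighted_median
    Estimate at the 50% point of the cumulative standardized
    inverse-variance weight over ordered ratios; SE by seeded parametric
    bootstrap.

Methods requiring >= 3 instruments return a structured NotEstimable
result rather than raising, so a proteome-wide scan never aborts on
sparse instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .harmonize import HarmonizedPair

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "bh_adjust",
    "Z95",
]

Z95 = 1.96  # conventional 95% multiplier on the log-odds scale


@dataclass(frozen=True)
class MRResult:
    """One MR estimate (or a structured not-estimable outcome)."""

    trait_id: str
    method: str  # wald | ivw_fe | ivw_mre | egger | weighted_median
    estimate: float
    se: float
    pval: float
    n_snp: int
    or_point: float
    or_lo95: float
    or_hi95: float
    p_adj: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None
    status: str = "ok"
    reason: str | None = None

    @property
    def estimable(self) -> bool:
        return self.status == "ok"


def _not_estimable(trait_id: str, method: str, n_snp: int, reason: str) -> MRResult:
    nan = float("nan")
    return MRResult(
        trait_id=trait_id,
        method=method,
        estimate=nan,
        se=nan,
        pval=nan,
        n_snp=n_snp,
        or_point=nan,
        or_lo95=nan,
        or_hi95=nan,
        status="not_estimable",
        reason=reason,
    )


def _result(
    trait_id: str,
    method: str,
    estimate: float,
    se: float,
    n_snp: int,
    pval: float | None = None,
    **kw,
) -> MRResult:
    if pval is None:
        pval = 2.0 * stats.norm.sf(abs(estimate / se)) if se > 0 else float("nan")
    return MRResult(
        trait_id=trait_id,
        method=method,
        estimate=estimate,
        se=se,
        pval=max(float(pval), 5e-324),
        n_snp=n_snp,
        or_point=math.exp(estimate),
        or_lo95=math.exp(estimate - Z95 * se),
        or_hi95=math.exp(estimate + Z95 * se),
        **kw,
    )


def wald_ratio(pair: HarmonizedPair, trait_id: str = "") -> MRResult:
    """Single-instrument ratio estimate beta_out / beta_exp.

    SE by the two-term first-order delta method:
    sqrt(se_out^2/beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    if not pair.usable:
        raise ValueError(f"{pair.variant_id}: pair is not usable ({pair.action})")
    bx, by = pair.beta_exp, pair.beta_out
    if bx == 0:
        raise ZeroDivisionError(f"{pair.variant_id}: degenerate instrument, beta_exp=0")
    estimate = by / bx
    var = pair.se_out**2 / bx**2 + (by**2 * pair.se_exp**2) / bx**4
    return _result(trait_id, "wald", estimate, math.sqrt(var), n_snp=1)


def _check_pairs(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    usable = [p for p in pairs if p.usable]
    for p in usable:
        if p.beta_exp == 0:
            raise ZeroDivisionError(f"{p.variant_id}: degenerate instrument, beta_exp=0")
    return usable


def ivw(
    pairs: Sequence[HarmonizedPair],
    effects_model: str = "multiplicative_random",
    trait_id: str = "",
) -> MRResult:
    """Inverse-variance-weighted average of per-instrument Wald ratios.

    First-order weights w_j = beta_exp_j^2 / se_out_j^2 make this a WLS
    fit of beta_out on beta_exp through the origin.  With one instrument
    it reduces exactly to the Wald ratio with se_exp treated as 0.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects_model {effects_model!r}")
    usable = _check_pairs(pairs)
    k = len(usable)
    if k == 0:
        raise ValueError("ivw requires at least one usable pair")
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    so = np.array([p.se_out for p in usable])
    w = bx**2 / so**2
    r = by / bx
    estimate = float(np.sum(w * r) / np.sum(w))
    se_fe = float(np.sqrt(1.0 / np.sum(w)))
    method = "ivw_fe"
    se = se_fe
    if effects_model == "multiplicative_random" and k >= 2:
        q = float(np.sum(w * (r - estimate) ** 2))
        se = se_fe * math.sqrt(max(1.0, q / (k - 1)))
        method = "ivw_mre"
    return _result(trait_id, method, estimate, se, n_snp=k)


def egger(pairs: Sequence[HarmonizedPair], trait_id: str = "") -> MRResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Exposure effects are oriented positive first (jointly negating the
    outcome effect), weights are 1/se_out^2, and the residual scale is
    floored at 1 (multiplicative random effects, never below fixed).
    Inference uses a t reference with k-2 df.  Fewer than 3 instruments
    yields a NotEstimable result, mirroring how underpowered sensitivity
    analyses are reported rather than raised.
    """
    usable = _check_pairs(pairs)
    k = len(usable)
    if k < 3:
        return _not_estimable(trait_id, "egger", k, "insufficient instruments")
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    so = np.array([p.se_out for p in usable])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip

    w = 1.0 / so**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    xty = WX.T @ by
    coef = np.linalg.solve(xtx, xty)
    resid = by - X @ coef
    dof = k - 2
    scale = float(resid @ (w * resid)) / dof
    cov_unscaled = np.linalg.inv(xtx)
    sigma = math.sqrt(scale)
    # multiplicative random effects with scale floored at 1
    infl = max(sigma, 1.0)
    se_int = float(math.sqrt(cov_unscaled[0, 0])) * infl
    se_slope = float(math.sqrt(cov_unscaled[1, 1])) * infl
    slope, intercept = float(coef[1]), float(coef[0])
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), dof)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), dof)
    return _result(
        trait_id,
        "egger",
        slope,
        se_slope,
        n_snp=k,
        pval=p_slope,
        egger_intercept=intercept,
        egger_intercept_p=float(p_int),
    )


def _wald_se(p: HarmonizedPair) -> float:
    return math.sqrt(
        p.se_out**2 / p.beta_exp**2 + (p.beta_out**2 * p.se_exp**2) / p.beta_exp**4
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    below = np.searchsorted(cum, 0.5, side="right") - 1
    if below < 0:
        return float(r[0])
    if below >= len(r) - 1:
        return float(r[-1])
    frac = (0.5 - cum[below]) / (cum[below + 1] - cum[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 2000,
    seed: int = 0,
    trait_id: str = "",
) -> MRResult:
    """Weighted-median MR estimate with parametric bootstrap SE.

    Wald ratios are ordered and the estimate taken where the cumulative
    standardized inverse-variance weight (1/se_wald^2) crosses 0.5, with
    linear interpolation between bracketing ratios; with equal weights
    this is the ordinary median.  The SE is the SD of re-estimates from
    ``n_boot`` draws of (beta_exp_j, beta_out_j) from their normal
    sampling distributions (seeded, reproducible).
    """
    usable = _check_pairs(pairs)
    k = len(usable)
    if k < 3:
        return _not_estimable(trait_id, "weighted_median", k, "insufficient instruments")
    bx = np.array([p.beta_exp for p in usable])
    by = np.array([p.beta_out for p in usable])
    sx = np.array([p.se_exp for p in usable])
    so = np.array([p.se_out for p in usable])

    ratios = by / bx
    weights = 1.0 / np.array([_wald_se(p) for p in usable]) ** 2
    estimate = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, so, size=(n_boot, k))
    bxs[bxs == 0] = np.finfo(float).tiny
    rs = bys / bxs
    vs = so**2 / bxs**2 + (bys**2 * sx**2) / bxs**4
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median(rs[i], 1.0 / vs[i])
    se = float(boots.std(ddof=1))
    return _result(trait_id, "weighted_median", estimate, se, n_snp=k)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone non-decreasing in rank, each <= 1; discovery at q < 0.05
    controls the false-discovery rate at 5%.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
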