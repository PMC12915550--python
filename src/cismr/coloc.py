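"""Bayesian colocalization under the five-hypothesis enumeration model.

For one genomic region and two traits, each assumed to harbor at most
one causal variant, the model enumerates the hypotheses

- H0: no causal variant for either trait,
- H1/H2: a causal variant for trait 1 only / trait 2 only,
- H3: distinct causal variants for the two traits,
- H4: one shared causal variant,

and assigns posterior probabilities from per-variant Wakefield
approximate Bayes factors against per-configuration priors (p1, p2 for
trait-specific causality, p12 for shared).  All aggregation is carried
out in log space, so z scores up to ~100 cause no overflow.

The conditional colocalization metric PP.H4/(PP.H3+PP.H4) — the
probability of a *shared* causal variant given a causal variant exists
for both traits — is exposed separately; it is informative when the
marginal PP.H4 is diluted by low regional power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "ColocInputRegion",
    "ColocResult",
    "wakefield_labf",
    "coloc_abf",
    "conditional_pp",
    "DEFAULT_PRIORS",
    "prior_effect_variance",
]

#: Field-standard single-variant priors: p1/p2 trait-specific, p12 shared.
DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)

#: Prior SD of true effects: 0.15 (SD units) for quantitative traits,
#: 0.2 (log-odds) for binary traits.
PRIOR_SD = {"quant": 0.15, "binary": 0.2}


def prior_effect_variance(trait_type: str) -> float:
    try:
        return PRIOR_SD[trait_type] ** 2
    except KeyError:
        raise ValueError(f"unknown trait_type {trait_type!r}") from None


@dataclass(frozen=True)
class ColocInputRegion:
    """Regional summary statistics for one trait, allele-aligned to the
    partner region (same variants, same order, same effect alleles)."""

    trait_id: str
    variant_ids: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quant"  # quant | binary; selects the prior W

    def __post_init__(self):
        beta = np.asarray(self.beta, dtype=float)
        se = np.asarray(self.se, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "se", se)
        if not (len(self.variant_ids) == beta.size == se.size):
            raise ValueError("variant_ids, beta, se lengths differ")
        if np.any(se <= 0):
            raise ValueError("all se must be > 0")
        prior_effect_variance(self.trait_type)  # validates

    def labf(self, w: float | None = None) -> np.ndarray:
        if w is None:
            w = prior_effect_variance(self.trait_type)
        return wakefield_labf(self.beta, self.se, w)


@dataclass(frozen=True)
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    n_variants: int
    p1: float
    p2: float
    p12: float

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])

    @property
    def conditional_pp(self) -> float:
        return conditional_pp(self)


def wakefield_labf(beta, se, w: float):
    """Log approximate Bayes factor for a single association estimate.

    With sampling variance V = se^2, shrinkage r = W/(W+V) and z =
    beta/se:  labf = 0.5*(log(1-r) + r*z^2).  Positive values favor a
    true effect; as W -> 0 the prior collapses to the null and the BF
    tends to 1 (labf -> 0).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if not w > 0:
        raise ValueError("prior effect variance w must be > 0")
    v = se**2
    r = w / (w + v)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return out if out.ndim else float(out)


def coloc_abf(
    region1: ColocInputRegion,
    region2: ColocInputRegion,
    p1: float = DEFAULT_PRIORS[0],
    p2: float = DEFAULT_PRIORS[1],
    p12: float = DEFAULT_PRIORS[2],
    w1: float | None = None,
    w2: float | None = None,
) -> ColocResult:
    """Posterior probabilities of H0-H4 for two aligned regions.

    Unnormalized (log) hypothesis masses, with S1 = sum_j BF1_j,
    S2 = sum_j BF2_j and S12 = sum_j BF1_j*BF2_j:

    - H0 ∝ 1
    - H1 ∝ p1*S1,  H2 ∝ p2*S2
    - H3 ∝ p1*p2*(S1*S2 - S12)   (distinct variants; exactly 0 when the
      region has a single variant)
    - H4 ∝ p12*S12

    The result is invariant to any joint permutation of the variants.
    """
    for p, name in ((p1, "p1"), (p2, "p2"), (p12, "p12")):
        if not p > 0:
            raise ValueError(f"{name} must be > 0")
    if p1 + p2 + p12 >= 0.01:
        raise ValueError("priors too large: p1+p2+p12 must be < 0.01")
    if region1.variant_ids != region2.variant_ids:
        if set(region1.variant_ids) == set(region2.variant_ids):
            raise ValueError("regions share variants but in different order; align first")
        raise ValueError("regions do not share the same variant set")

    l1 = np.atleast_1d(region1.labf(w1))
    l2 = np.atleast_1d(region2.labf(w2))
    n = l1.size

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = math.log(p1) + ls1
    lh[2] = math.log(p2) + ls2
    lh[4] = math.log(p12) + ls12
    # log(S1*S2 - S12) via log1p(-exp(ls12 - ls1 - ls2)); the cross-term
    # sum always dominates, with equality exactly when n == 1.
    diff = ls12 - (ls1 + ls2)
    if n == 1 or diff >= 0.0:
        lh[3] = -np.inf
    else:
        lh[3] = math.log(p1) + math.log(p2) + ls1 + ls2 + math.log1p(-math.exp(diff))

    norm = logsumexp(lh)
    pp = np.exp(lh - norm)
    return ColocResult(
        pp_h0=float(pp[0]),
        pp_h1=float(pp[1]),
        pp_h2=float(pp[2]),
        pp_h3=float(pp[3]),
        pp_h4=float(pp[4]),
        n_variants=n,
        p1=p1,
        p2=p2,
        p12=p12,
    )


def conditional_pp(result: ColocResult) -> float:
    """PP.H4 / (PP.H3 + PP.H4); NaN when no causal-for-both mass exists."""
    denom = result.pp_h3 + result.pp_h4
    if denom == 0:
        return float("nan")
    return result.pp_h4 / denom
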