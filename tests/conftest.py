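"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive (brute force, enumeration, direct
definitions) and never share code with the implementation paths they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cismr.harmonize import HarmonizedPair
from cismr.sumstats import VariantAssoc


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=100,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=None,
    eaf=0.3,
    n=10000,
) -> VariantAssoc:
    if pval is None:
        from scipy.stats import norm

        pval = max(2 * norm.sf(abs(beta / se)), 5e-324)
    return VariantAssoc(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


def make_pair(bx, sx, by, so, eaf_exp=0.3, eaf_out=0.3, vid="rs1") -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=vid,
        beta_exp=bx,
        se_exp=sx,
        eaf_exp=eaf_exp,
        beta_out=by,
        se_out=so,
        eaf_out=eaf_out,
        action="kept_same",
    )


# ---------------------------------------------------------------- oracles


def bh_bruteforce(pvals) -> np.ndarray:
    """Quadratic-time BH from the definition: adj(j) = min over ranks
    i >= rank(j) of m*p_(i)/i, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for jj, j in enumerate(order):
        candidates = [
            m * p[order[ii]] / (ii + 1) for ii in range(jj, m)
        ]
        adj[j] = min(1.0, min(candidates))
    return adj


def coloc_enumeration_oracle(l1, l2, p1, p2, p12) -> np.ndarray:
    """Direct enumeration over all per-trait causal configurations.

    Configurations: (none, none) -> H0; (j, none) -> H1; (none, j) ->
    H2; (j, k), j != k -> H3; (j, j) -> H4.  Every configuration's mass
    is scaled by the constant exp(-c1-c2) (c = max log-BF per trait) so
    plain-float sums never overflow; the constant cancels on
    normalization.
    """
    c1, c2 = max(l1), max(l2)
    bf1 = [math.exp(v - c1) for v in l1]
    bf2 = [math.exp(v - c2) for v in l2]
    n = len(bf1)
    mass = [0.0] * 5
    mass[0] = math.exp(-c1) * math.exp(-c2)
    for j in range(n):
        mass[1] += p1 * bf1[j] * math.exp(-c2)
        mass[2] += math.exp(-c1) * p2 * bf2[j]
    for j, k in itertools.product(range(n), range(n)):
        if j == k:
            mass[4] += p12 * bf1[j] * bf2[j]
        else:
            mass[3] += p1 * p2 * bf1[j] * bf2[k]
    total = sum(mass)
    return np.array([m / total for m in mass])


def orientation_cases(ea, oa, beta, eaf):
    """The 8 orientation cases of one exposure/outcome record pair:
    the exposure reported per either of its two allele codings, crossed
    with the outcome reported swapped and/or on the opposite strand.
    ``expected`` is the aligned outcome beta relative to the exposure
    record's stated effect allele."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rc = lambda a: comp[a]
    cases = []
    for exp_swap in (False, True):
        e1, e2 = (oa, ea) if exp_swap else (ea, oa)
        expected = -beta if exp_swap else beta
        exp_eaf = 1 - eaf if exp_swap else eaf
        for out_swap in (False, True):
            for strand in (False, True):
                a1, a2, b, f = ea, oa, beta, eaf
                if out_swap:
                    a1, a2, b, f = a2, a1, -b, 1 - f
                if strand:
                    a1, a2 = rc(a1), rc(a2)
                cases.append(
                    {
                        "exp_ea": e1,
                        "exp_oa": e2,
                        "exp_eaf": exp_eaf,
                        "ea": a1,
                        "oa": a2,
                        "beta": b,
                        "eaf": f,
                        "expected": expected,
                        "expected_eaf": 1 - eaf if exp_swap else eaf,
                    }
                )
    return cases
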