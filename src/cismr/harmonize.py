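"""Allele harmonization of exposure and outcome association records.

Two-sample MR requires the exposure and outcome effects at each variant
to be expressed per the *same* effect allele.  The outcome record can be
reported in one of four recoverable orientations relative to the
exposure: same alleles, swapped alleles, opposite strand, or opposite
strand with swapped alleles.  Palindromic SNPs (A/T or C/G) cannot be
disambiguated by strand and are either dropped or resolved from allele
frequency concordance; no proxy-variant substitution is attempted —
variants absent from the outcome are reported unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .sumstats import TraitTable, VariantAssoc

__all__ = [
    "HarmonizedPair",
    "align_pair",
    "harmonize_tables",
    "reverse_complement",
    "is_palindromic",
    "KEPT_ACTIONS",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Actions under which a pair carries usable, allele-aligned betas.
KEPT_ACTIONS = frozenset({"kept_same", "flipped", "strand_corrected"})


def reverse_complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1]


def _is_snp(*alleles: str) -> bool:
    return all(len(a) == 1 and a in "ACGT" for a in alleles)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G pair: strand flips are indistinguishable from swaps."""
    return _is_snp(effect_allele, other_allele) and reverse_complement(
        effect_allele
    ) == other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    For dropped actions the outcome fields carry no usable values
    (``None``) and ``reason`` names the cause.
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float | None
    beta_out: float | None
    se_out: float | None
    eaf_out: float | None
    action: str
    reason: str | None = None

    @property
    def usable(self) -> bool:
        return self.action in KEPT_ACTIONS


def _dropped(exp: VariantAssoc, action: str, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        eaf_exp=exp.eaf,
        beta_out=None,
        se_out=None,
        eaf_out=None,
        action=action,
        reason=reason,
    )


def _aligned(
    exp: VariantAssoc, out: VariantAssoc, action: str, negate: bool
) -> HarmonizedPair:
    beta_out = -out.beta if negate else out.beta
    eaf_out = out.eaf
    if negate and eaf_out is not None:
        eaf_out = 1.0 - eaf_out
    return HarmonizedPair(
        variant_id=exp.variant_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        eaf_exp=exp.eaf,
        beta_out=beta_out,
        se_out=out.se,
        eaf_out=eaf_out,
        action=action,
    )


def align_pair(
    exp: VariantAssoc,
    out: VariantAssoc,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> HarmonizedPair:
    """Align one outcome record to the exposure's effect allele.

    Parameters
    ----------
    palindrome_policy
        ``"drop"`` discards every palindromic SNP; ``"infer_by_eaf"``
        keeps those whose effect-allele frequency in *both* traits lies
        farther than ``eaf_window`` from 0.5 and orients them so the
        frequencies are concordant (both < 0.5 or both > 0.5).
    eaf_window
        Half-width of the ambiguity zone around 0.5 (default 0.08, i.e.
        drop when MAF is in [0.42, 0.5]).
    """
    if exp.variant_id != out.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exp.variant_id!r} vs {out.variant_id!r}"
        )
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    e1, e2 = exp.effect_allele, exp.other_allele
    o1, o2 = out.effect_allele, out.other_allele

    if is_palindromic(e1, e2):
        if {o1, o2} != {e1, e2}:
            return _dropped(exp, "dropped_mismatch", "allele_mismatch")
        if palindrome_policy == "drop":
            return _dropped(exp, "dropped_palindromic", "palindromic_policy_drop")
        if exp.eaf is None or out.eaf is None:
            return _dropped(exp, "dropped_palindromic", "palindromic_missing_eaf")
        if (
            abs(exp.eaf - 0.5) <= eaf_window
            or abs(out.eaf - 0.5) <= eaf_window
        ):
            return _dropped(exp, "dropped_palindromic", "palindromic_ambiguous_eaf")
        # Nominal string orientation, then force frequency concordance:
        # for a palindrome the strand is unknowable, so eaf carries the
        # full alignment information.
        negate = o1 != e1
        eaf_aligned = 1.0 - out.eaf if negate else out.eaf
        if (exp.eaf < 0.5) != (eaf_aligned < 0.5):
            negate = not negate
        return _aligned(exp, out, "flipped" if negate else "kept_same", negate)

    # Non-palindromic: direct match, swap, or (SNPs only) strand flip.
    if (o1, o2) == (e1, e2):
        return _aligned(exp, out, "kept_same", negate=False)
    if (o1, o2) == (e2, e1):
        return _aligned(exp, out, "flipped", negate=True)
    if _is_snp(e1, e2, o1, o2):
        r1, r2 = reverse_complement(o1), reverse_complement(o2)
        if (r1, r2) == (e1, e2):
            return _aligned(exp, out, "strand_corrected", negate=False)
        if (r1, r2) == (e2, e1):
            return _aligned(exp, out, "strand_corrected", negate=True)
    return _dropped(exp, "dropped_mismatch", "allele_mismatch")


def harmonize_tables(
    exp: TraitTable,
    out: TraitTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
) -> tuple[list[HarmonizedPair], dict[str, int]]:
    """Harmonize every exposure variant present in the outcome table.

    Returns all pairs (usable and dropped) plus a tally covering every
    exposure variant: each is either harmonized with one action, or
    counted ``unavailable`` when absent from the outcome.
    """
    pairs: list[HarmonizedPair] = []
    tally: dict[str, int] = {"unavailable": 0}
    for rec in exp.records():
        if rec.variant_id not in out:
            tally["unavailable"] += 1
            continue
        pair = align_pair(
            rec, out.get(rec.variant_id), palindrome_policy, eaf_window
        )
        pairs.append(pair)
        tally[pair.action] = tally.get(pair.action, 0) + 1
    return pairs, tally
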