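"""Allele harmonization: orientation recovery, palindromes, involution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismr.harmonize import align_pair, harmonize_tables, is_palindromic
from cismr.mr import ivw
from cismr.sumstats import TraitTable
from conftest import make_variant, orientation_cases


def test_swapped_alleles_flip_beta_and_eaf():
    exp = make_variant(ea="A", oa="G", beta=0.10, eaf=0.30)
    out = make_variant(ea="G", oa="A", beta=0.05, eaf=0.30)
    pair = align_pair(exp, out)
    assert pair.action == "flipped"
    assert pair.beta_out == pytest.approx(-0.05)
    assert pair.eaf_out == pytest.approx(0.70)


def test_strand_flip_recovered_without_negation():
    exp = make_variant(ea="A", oa="G", beta=0.10)
    out = make_variant(ea="T", oa="C", beta=0.05)
    pair = align_pair(exp, out)
    assert pair.action == "strand_corrected"
    assert pair.beta_out == pytest.approx(+0.05)


def test_ambiguous_palindrome_dropped():
    exp = make_variant(ea="A", oa="T", eaf=0.50)
    out = make_variant(ea="A", oa="T", eaf=0.50)
    pair = align_pair(exp, out, palindrome_policy="infer_by_eaf", eaf_window=0.08)
    assert pair.action == "dropped_palindromic"
    assert pair.beta_out is None


def test_palindrome_policies():
    exp = make_variant(ea="C", oa="G", beta=0.1, eaf=0.2)
    out = make_variant(ea="C", oa="G", beta=0.05, eaf=0.2)
    assert align_pair(exp, out, "drop").action == "dropped_palindromic"
    kept = align_pair(exp, out, "infer_by_eaf")
    assert kept.action == "kept_same" and kept.beta_out == pytest.approx(0.05)
    # discordant frequencies imply the other orientation
    out_disc = make_variant(ea="C", oa="G", beta=0.05, eaf=0.8)
    flipped = align_pair(exp, out_disc, "infer_by_eaf")
    assert flipped.action == "flipped"
    assert flipped.beta_out == pytest.approx(-0.05)
    assert flipped.eaf_out == pytest.approx(0.2)
    # missing eaf under infer_by_eaf: dropped with a distinct reason
    out_noeaf = make_variant(ea="C", oa="G", beta=0.05, eaf=None)
    dropped = align_pair(exp, out_noeaf, "infer_by_eaf")
    assert dropped.action == "dropped_palindromic"
    assert dropped.reason == "palindromic_missing_eaf"


def test_irreconcilable_alleles_dropped():
    exp = make_variant(ea="A", oa="G")
    out = make_variant(ea="A", oa="C")
    assert align_pair(exp, out).action == "dropped_mismatch"
    # indels: exact/swap only, no strand logic
    exp_i = make_variant(ea="AT", oa="A")
    out_i = make_variant(ea="A", oa="AT", beta=0.05)
    assert align_pair(exp_i, out_i).action == "flipped"
    out_rc = make_variant(ea="TA", oa="T", beta=0.05)
    assert align_pair(exp_i, out_rc).action == "dropped_mismatch"


def test_mismatched_variant_id_is_programming_error():
    with pytest.raises(ValueError, match="variant_id"):
        align_pair(make_variant(variant_id="rs1"), make_variant(variant_id="rs2"))


def test_orientation_enumeration_oracle():
    """All 8 reporting orientations (exposure coding x outcome swap x
    outcome strand) recover the aligned beta the oracle predicts."""
    rng = np.random.default_rng(11)
    pairs_checked = 0
    for i in range(100):
        ea, oa = [("A", "G"), ("A", "C"), ("T", "G"), ("C", "T")][i % 4]
        beta_out_true = float(rng.normal())
        eaf = float(rng.uniform(0.05, 0.95))
        for case in orientation_cases(ea, oa, beta_out_true, eaf):
            exp = make_variant(
                variant_id=f"rs{i}", ea=case["exp_ea"], oa=case["exp_oa"],
                beta=0.1, eaf=case["exp_eaf"],
            )
            out = make_variant(
                variant_id=f"rs{i}",
                ea=case["ea"],
                oa=case["oa"],
                beta=case["beta"],
                eaf=case["eaf"],
            )
            pair = align_pair(exp, out)
            assert pair.usable
            assert pair.beta_out == pytest.approx(case["expected"])
            if pair.eaf_out is not None:
                assert pair.eaf_out == pytest.approx(case["expected_eaf"])
            pairs_checked += 1
    assert pairs_checked == 800


def test_involution():
    """Harmonizing an already-harmonized pair changes nothing."""
    rng = np.random.default_rng(5)
    for i in range(50):
        ea, oa = [("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")][i % 4]
        exp = make_variant(variant_id=f"rs{i}", ea=ea, oa=oa, beta=0.2,
                           eaf=float(rng.uniform(0.05, 0.95)))
        out = make_variant(variant_id=f"rs{i}", ea=oa, oa=ea,
                           beta=float(rng.normal()), eaf=float(rng.uniform(0.05, 0.95)))
        first = align_pair(exp, out)
        assert first.action == "flipped"
        # re-express the harmonized outcome as a record and align again
        out2 = make_variant(variant_id=f"rs{i}", ea=ea, oa=oa,
                            beta=first.beta_out, eaf=first.eaf_out)
        second = align_pair(exp, out2)
        assert second.action == "kept_same"
        assert second.beta_out == first.beta_out
        assert second.eaf_out == first.eaf_out


def test_harmonize_tables_availability_tally():
    exp = TraitTable.from_records(
        "P1", "protein", "plat",
        [make_variant(variant_id=f"rs{i}", pos=100 + i) for i in range(3)],
    )
    out = TraitTable.from_records(
        "O", "outcome", "gwas",
        [make_variant(variant_id=f"rs{i}", pos=100 + i, beta=0.05) for i in range(2)],
    )
    pairs, tally = harmonize_tables(exp, out)
    assert len(pairs) == 2
    assert tally["unavailable"] == 1
    assert all(p.action == "kept_same" for p in pairs)
    # every exposure variant receives exactly one outcome
    assert sum(tally.values()) == len(exp)


def test_downstream_invariance_to_outcome_file_orientation():
    """Flipping the outcome file's allele columns (negating beta,
    complementing eaf) must leave the IVW estimate unchanged."""
    from cismr.synth import simulate_mr_study

    exp, out = simulate_mr_study(6, 0.25, seed=99, randomize_orientation=True)
    flipped_df = out.df.copy()
    flipped_df[["effect_allele", "other_allele"]] = flipped_df[
        ["other_allele", "effect_allele"]
    ].to_numpy()
    flipped_df["beta"] = -flipped_df["beta"]
    flipped_df["eaf"] = 1.0 - flipped_df["eaf"]
    out_flipped = TraitTable("O", "outcome", "gwas", flipped_df)

    est = []
    for o in (out, out_flipped):
        pairs, _ = harmonize_tables(exp, o)
        est.append(ivw([p for p in pairs if p.usable]).estimate)
    assert est[0] == pytest.approx(est[1], abs=0, rel=1e-14)


@given(
    st.sampled_from([("A", "G"), ("T", "C"), ("A", "T"), ("C", "G")]),
    st.floats(-1, 1, allow_nan=False),
    st.floats(0.05, 0.95),
)
@settings(max_examples=100, deadline=None)
def test_every_pair_gets_exactly_one_action(alleles, beta, eaf):
    ea, oa = alleles
    exp = make_variant(ea=ea, oa=oa, eaf=eaf)
    out = make_variant(ea=oa, oa=ea, beta=beta, eaf=1 - eaf)
    pair = align_pair(exp, out)
    assert pair.action in {
        "kept_same", "flipped", "strand_corrected",
        "dropped_palindromic", "dropped_mismatch",
    }
    if not pair.usable:
        assert pair.beta_out is None and pair.se_out is None
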