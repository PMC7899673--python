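"""Binding-site search with the 3'-anchored mismatch model; amplicons."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeprimer.insilico import (
    MismatchPolicy,
    PrimerPair,
    find_binding_sites,
    predict_amplicons,
    success_matrix,
)
from barcodeprimer.iupac import IUPAC_CODES, Primer, degeneracy, expand, reverse_complement
from barcodeprimer.seqio import SequenceRecord

iupac_primers = st.text(alphabet=sorted(IUPAC_CODES), min_size=2, max_size=12).filter(
    lambda s: degeneracy(s) <= 256
)
templates = st.text(alphabet="ACGT", min_size=12, max_size=40)

STRICT = MismatchPolicy(max_total_mismatches=0, three_prime_window=0)


def test_exact_forward_site():
    sites = find_binding_sites(
        Primer("p", "ACGT", "forward"), SequenceRecord("t", "TTACGTTT"), STRICT
    )
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.end, s.strand, s.total_mismatches) == (3, 6, "plus", 0)


def test_three_prime_window_vetoes_terminal_mismatch():
    primer = Primer("p", "ACGT", "forward")
    template = SequenceRecord("t", "TTACGATT")  # ACGA at 3..6: mismatch at primer pos 4
    lenient = MismatchPolicy(max_total_mismatches=1, three_prime_window=0)
    assert [(s.start, s.total_mismatches) for s in find_binding_sites(primer, template, lenient)] == [(3, 1)]
    anchored = MismatchPolicy(max_total_mismatches=1, three_prime_window=2,
                              max_three_prime_mismatches=0)
    assert find_binding_sites(primer, template, anchored) == []


def test_reverse_primer_scanned_as_reverse_complement():
    # reverse primer 5'-ACGT-3' anneals where the plus strand reads ACGT (its rc)
    primer = Primer("r", "ACGT", "reverse")
    sites = find_binding_sites(primer, SequenceRecord("t", "GGACGTGG"), STRICT)
    assert len(sites) == 1 and sites[0].strand == "minus"
    assert (sites[0].start, sites[0].end) == (3, 6)


def test_reverse_three_prime_window_faces_into_amplicon():
    # reverse primer rc = ACGT on template; its 3' end is the template-LEFT end.
    # Mismatch at template-left position must veto; at template-right must not.
    primer = Primer("r", "ACGT", "reverse")  # rc = ACGT
    anchored = MismatchPolicy(max_total_mismatches=1, three_prime_window=2,
                              max_three_prime_mismatches=0)
    left_mm = SequenceRecord("t", "GGCCGTGG")   # ?CGT: mismatch at left (3' side)
    right_mm = SequenceRecord("t", "GGACGAGG")  # ACG?: mismatch at right (5' side)
    assert find_binding_sites(primer, left_mm, anchored) == []
    assert len(find_binding_sites(primer, right_mm, anchored)) == 1


def test_template_gaps_and_short_templates_rejected():
    with pytest.raises(ValueError, match="gaps"):
        find_binding_sites(Primer("p", "AC", "forward"), SequenceRecord("t", "A-CT"))
    with pytest.raises(ValueError, match="longer"):
        find_binding_sites(Primer("p", "ACGTACGT", "forward"), SequenceRecord("t", "ACGT"))


@given(iupac_primers, templates)
@settings(max_examples=100)
def test_zero_mismatch_sites_equal_expansion_scan(primer_seq, template_seq):
    """IUPAC matching must equal the union of exact scans over all expansions."""
    template = SequenceRecord("t", template_seq)
    for orientation in ("forward", "reverse"):
        primer = Primer("p", primer_seq, orientation)
        if len(primer_seq) > len(template_seq):
            continue
        sites = find_binding_sites(primer, template, STRICT)
        L = len(primer_seq)
        variants = expand(
            primer_seq if orientation == "forward" else reverse_complement(primer_seq),
            cap=256,
        )
        expected = sorted(
            o + 1
            for o in range(len(template_seq) - L + 1)
            if template_seq[o : o + L] in variants
        )
        assert sorted(s.start for s in sites) == expected


@given(iupac_primers, templates)
def test_strand_symmetry_under_template_reverse_complement(primer_seq, template_seq):
    """Sites of a forward primer map to mirror-image minus-strand sites of the
    same sequence used as a reverse primer on the reverse-complemented template."""
    if len(primer_seq) > len(template_seq):
        return
    policy = MismatchPolicy(max_total_mismatches=2, three_prime_window=2,
                            max_three_prime_mismatches=1)
    fwd = find_binding_sites(
        Primer("p", primer_seq, "forward"), SequenceRecord("t", template_seq), policy
    )
    rev = find_binding_sites(
        Primer("p", primer_seq, "reverse"),
        SequenceRecord("t", reverse_complement(template_seq)),
        policy,
    )
    L = len(template_seq)
    assert sorted((L - s.end + 1, L - s.start + 1, s.total_mismatches,
                   s.three_prime_mismatches, s.mismatch_mask) for s in fwd) == sorted(
        (s.start, s.end, s.total_mismatches, s.three_prime_mismatches, s.mismatch_mask)
        for s in rev
    )


@given(iupac_primers, templates, st.integers(0, 3), st.integers(0, 2), st.integers(0, 2))
@settings(max_examples=60)
def test_relaxing_policy_never_removes_sites(primer_seq, template_seq, total, window, three):
    if len(primer_seq) > len(template_seq):
        return
    three = min(three, total)
    primer = Primer("p", primer_seq, "forward")
    template = SequenceRecord("t", template_seq)
    tight = MismatchPolicy(total, window, three)
    loose = MismatchPolicy(total + 1, max(window - 1, 0), min(three + 1, total + 1))
    starts_tight = {s.start for s in find_binding_sites(primer, template, tight)}
    starts_loose = {s.start for s in find_binding_sites(primer, template, loose)}
    assert starts_tight <= starts_loose


def test_amplicon_geometry_and_product_length():
    template = SequenceRecord("t", "G" * 20 + "AACCAA" + "G" * 100 + "TTGGTT" + "G" * 20)
    fwd = Primer("f", "AACCAA", "forward")
    rev = Primer("r", "AACCAA", "reverse")  # rc = TTGGTT
    amps = predict_amplicons(fwd, rev, template, STRICT, (50, 200))
    assert len(amps) == 1
    a = amps[0]
    assert a.forward_site.start == 21 and a.reverse_site.end == 132
    assert a.product_length == 132 - 21 + 1
    assert a.product_length >= len(fwd.sequence) + len(rev.sequence)
    # out-of-range product excluded
    assert predict_amplicons(fwd, rev, template, STRICT, (400, 1000)) == []


def test_amplicon_requires_forward_before_reverse():
    template = SequenceRecord("t", "TTGGTT" + "G" * 50 + "AACCAA")
    fwd = Primer("f", "AACCAA", "forward")
    rev = Primer("r", "AACCAA", "reverse")
    assert predict_amplicons(fwd, rev, template, STRICT, (1, 1000)) == []


def _panel():
    core = "G" * 100
    recs = [
        SequenceRecord(f"x{i}", "T" * 10 + "AACCAA" + core + "TTGGTT" + "T" * 10)
        for i in range(3)
    ] + [
        SequenceRecord(f"y{i}", "T" * 10 + "AACCAA" + core + "TTGGTA" + "T" * 10)
        for i in range(2)
    ]
    return recs


def test_success_matrix_rates_and_weighted_average():
    pair_ok = PrimerPair("ok", Primer("f", "AACCAA", "forward"),
                         Primer("r", "AACCAA", "reverse"))
    pair_dead = PrimerPair("dead", Primer("f", "CCCCCC", "forward"),
                           Primer("r", "CCCCCC", "reverse"))
    groups = {f"x{i}": "X" for i in range(3)} | {f"y{i}": "Y" for i in range(2)}
    table = success_matrix([pair_ok, pair_dead], _panel(), groups, STRICT, (50, 200))
    t = table.set_index(["pair", "group"])["success"]
    assert t[("ok", "X")] == 1.0
    assert t[("ok", "Y")] == 0.0  # 3' mismatch in the reverse anchor
    assert t[("ok", "overall")] == pytest.approx(3 / 5)
    assert (table[table["pair"] == "dead"]["success"] == 0.0).all()
    # weighted group average equals the overall rate
    sub = table[(table["pair"] == "ok") & (table["group"] != "overall")]
    weighted = (sub["success"] * sub["n_records"]).sum() / sub["n_records"].sum()
    assert weighted == pytest.approx(t[("ok", "overall")])


def test_success_matrix_rejects_empty_references():
    pair = PrimerPair("p", Primer("f", "AC", "forward"), Primer("r", "AC", "reverse"))
    with pytest.raises(ValueError, match="empty"):
        success_matrix([pair], [])
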