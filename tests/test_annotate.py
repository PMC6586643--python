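"""Signal prediction, cleavage-site detection, excision and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holopept import (
    AnnotationError,
    PipelineConfig,
    PrecursorRecord,
    Segment,
    annotate_precursor,
    classify_segment,
    count_copies,
    excise_peptides,
    find_cleavage_sites,
    predict_signal_region,
)
from holopept.annotate import BASIC

# ---------------------------------------------------------------------------
# signal region
# ---------------------------------------------------------------------------


def test_provided_mode_echoes_boundary():
    sr = predict_signal_region("A" * 60, mode="provided", provided_end=24)
    assert (sr.end, sr.mode) == (24, "provided")


def test_provided_boundary_must_fit():
    with pytest.raises(AnnotationError):
        predict_signal_region("A" * 20, mode="provided", provided_end=20)
    with pytest.raises(AnnotationError):
        predict_signal_region("A" * 60, mode="provided", provided_end=9)


def test_heuristic_needs_30_residues():
    with pytest.raises(AnnotationError, match="too short"):
        predict_signal_region("A" * 20)


def test_heuristic_finds_planted_boundary():
    """Hydrophobic core + (-3,-1) small-residue motif is found within +-2
    of the planted cut in >= 80% of 100 seeded polar-tail draws."""
    rng = np.random.default_rng(42)
    polar = list("NQSTDEHG")
    hits = 0
    for _ in range(100):
        tail = "".join(rng.choice(polar, size=40))
        sr = predict_signal_region("M" + "L" * 16 + "ASA" + tail)
        hits += abs(sr.end - 20) <= 2
    assert hits >= 80


# ---------------------------------------------------------------------------
# cleavage sites
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seq, expected", [
    ("AAKRAA", [(3, 4, "dibasic", "KR")]),
    ("AAKKRAA", [(3, 5, "tribasic", "KKR")]),
    ("AARPAA", []),                       # single R before P never cleaves
    ("AKAARAA", [(5, 5, "monobasic", "R")]),   # K at -3 licenses the R
    ("AAKRRKAA", [(3, 6, "tribasic", "KRRK")]),  # 4-run: one merged site
    ("KRAAKR", [(1, 2, "dibasic", "KR"), (5, 6, "dibasic", "KR")]),
])
def test_site_detection(seq, expected):
    sites = find_cleavage_sites(seq, monobasic_mode="strict")
    assert [(s.start, s.end, s.kind, s.residues) for s in sites] == expected


def _brute_force_sites(seq, mode):
    """Independent re-statement of the cleavage rule, position by position."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] in "KR":
            j = i
            while j < len(seq) and seq[j] in "KR":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    out = []
    for i, j in runs:
        if j - i >= 2:
            out.append((i + 1, j))
        elif mode != "off":
            before_p = j < len(seq) and seq[j] == "P"
            upstream = any(i - d >= 0 and seq[i - d] in "KR" for d in (3, 5, 7))
            strict_ok = upstream and not before_p
            permissive_ok = strict_ok or (seq[i] == "R" and not before_p)
            if strict_ok or (mode == "permissive" and permissive_ok):
                out.append((i + 1, j))
    return out


@given(seq=st.text(alphabet="AKRP", min_size=1, max_size=30),
       mode=st.sampled_from(["strict", "permissive", "off"]))
@settings(max_examples=400, deadline=None)
def test_sites_agree_with_brute_force(seq, mode):
    got = [(s.start, s.end) for s in find_cleavage_sites(seq, mode)]
    assert got == _brute_force_sites(seq, mode)


@given(seq=st.text(alphabet="ACKRPGQ", min_size=1, max_size=40))
@settings(max_examples=200, deadline=None)
def test_permissive_superset_of_strict(seq):
    strict = {(s.start, s.end) for s in find_cleavage_sites(seq, "strict")}
    permissive = {(s.start, s.end) for s in find_cleavage_sites(seq, "permissive")}
    assert strict <= permissive


def test_offset_excludes_signal_region():
    seq = "MKRLLLLLLLLAAKRAA"
    assert find_cleavage_sites(seq, offset=11)[0].start == 14
    # the KR at 2-3 is inside the excluded region
    assert all(s.start > 11 for s in find_cleavage_sites(seq, offset=11))


# ---------------------------------------------------------------------------
# excision
# ---------------------------------------------------------------------------


def _toy(seq):
    return PrecursorRecord(id="t", sequence=seq)


def test_excision_between_signal_and_sites():
    sig24 = "M" + "L" * 20 + "ASA"
    tail = "N" * 30
    seq = sig24 + "CFITNCPLGG" + "KR" + tail
    signal = predict_signal_region(seq, "provided", provided_end=24)
    sites = find_cleavage_sites(seq, offset=24)
    segments = excise_peptides(_toy(seq), signal, sites)
    assert [(s.sequence, s.c_term_context) for s in segments] == [
        ("CFITNCPLGG", "cleavage_site"), (tail, "precursor_end")]
    assert segments[0].n_term_context == "signal"


def test_adjacent_sites_no_empty_segment():
    seq = "M" + "L" * 20 + "ASA" + "AAAA" + "KRKR" + "N" * 20
    signal = predict_signal_region(seq, "provided", provided_end=24)
    sites = find_cleavage_sites(seq, offset=24)
    segments = excise_peptides(_toy(seq), signal, sites)
    assert all(s.sequence for s in segments)


def test_no_sites_single_segment():
    seq = "M" + "L" * 20 + "ASA" + "N" * 20
    signal = predict_signal_region(seq, "provided", provided_end=24)
    segments = excise_peptides(_toy(seq), signal, [])
    assert len(segments) == 1 and segments[0].sequence == "N" * 20


def test_excision_signal_past_end_errors():
    with pytest.raises(AnnotationError):
        excise_peptides(_toy("A" * 12),
                        predict_signal_region("A" * 13, "provided",
                                              provided_end=12), [])


@given(seq=st.text(alphabet="ACDEFGKRLNPQS", min_size=30, max_size=120),
       end=st.integers(min_value=10, max_value=28))
@settings(max_examples=200, deadline=None)
def test_residue_conservation(seq, end):
    """Signal + site + segment residues partition the precursor exactly."""
    signal = predict_signal_region(seq, "provided", provided_end=end)
    sites = find_cleavage_sites(seq, "strict", offset=end)
    segments = excise_peptides(_toy(seq), signal, sites)
    pieces = [(1, end, seq[:end])]
    pieces += [(s.start, s.end, s.residues) for s in sites]
    pieces += [(s.start, s.end, s.sequence) for s in segments]
    pieces.sort()
    assert "".join(p[2] for p in pieces) == seq
    assert sum(p[1] - p[0] + 1 for p in pieces) == len(seq)


# ---------------------------------------------------------------------------
# classification and copy counting
# ---------------------------------------------------------------------------


def _segment(seq):
    return Segment(precursor_id="t", start=1, end=len(seq), sequence=seq,
                   n_term_context="cleavage_site", c_term_context="cleavage_site")


@pytest.mark.parametrize("seq, label, n_acidic", [
    ("APLADDTAHQVDE", "acidic_spacer", 4),     # detected spacer peptide
    ("GRQPNRNAHYRTLPF", "bioactive_candidate", 0),
    ("AA", "unassigned", 0),
    ("MPMNPADYFSRGTVYIPTRDS", "bioactive_candidate", 2),
])
def test_classification(seq, label, n_acidic):
    cls = classify_segment(_segment(seq))
    assert cls.label == label
    assert cls.acidic_count == n_acidic


def test_count_copies():
    assert count_copies(["QYFAG", "QYFAG", "QFFQG"]) == {"QYFAG": 2, "QFFQG": 1}
    assert count_copies([]) == {}


# ---------------------------------------------------------------------------
# full annotation
# ---------------------------------------------------------------------------


def test_poly_alanine_not_candidate():
    ann = annotate_precursor(PrecursorRecord(id="a", sequence="A" * 100))
    assert ann.candidate_precursor is False


def test_annotation_deterministic():
    seq = "M" + "L" * 20 + "ASA" + "EDDSAEN" + "KR" + "QLPGSPWKFWEG" + "KR" + "N" * 20
    cfg = PipelineConfig(signal_mode="provided", signal_provided_map={"x": 24})
    a = annotate_precursor(PrecursorRecord(id="x", sequence=seq), cfg)
    b = annotate_precursor(PrecursorRecord(id="x", sequence=seq), cfg)
    assert [str(p) for p in a.mature_peptides] == [str(p) for p in b.mature_peptides]
    assert a.copy_counts == b.copy_counts
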