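"""Candidate indexing, peak matching and target-decoy FDR."""

import pytest

from holopept import (
    CandidateIndex,
    MaturePeptide,
    Modification,
    PeakObservation,
    PipelineConfig,
    PrecursorRecord,
    SimConfig,
    annotate_precursor,
    best_matches,
    build_candidate_index,
    estimate_fdr,
    generate_peak_list,
    generate_precursor_set,
    make_decoys,
    mass_to_charge,
    match_peaks,
    peptide_mass,
    run_search,
)
from holopept.match import IndexEntry, MatchResult


def _entry(core, mods=(), decoy=False):
    pep = MaturePeptide(core_sequence=core, mods=tuple(mods),
                        precursor_id="p", start=1, end=len(core))
    return IndexEntry(peptide=pep, neutral_mass=peptide_mass(core, mods),
                      is_decoy=decoy)


def test_make_decoys():
    recs = [PrecursorRecord(id="p1", sequence="MKTA")]
    decoys = make_decoys(recs)
    assert decoys[0].id == "DECOY_p1"
    assert decoys[0].sequence == "ATKM"
    assert len(decoys) == len(recs)


def test_palindromic_decoy_equals_target():
    rec = PrecursorRecord(id="pal", sequence="MKAAKM")
    assert make_decoys([rec])[0].sequence == rec.sequence


def test_index_length_window(toy_annotations):
    index = build_candidate_index(toy_annotations.values())
    cores = {e.peptide.core_sequence for e in index.entries}
    assert "QLPGSPWKFWE" in cores                 # 11-mer detected peptide
    assert "QYFA" not in cores                    # tetrapeptides undetectable
    assert all(8 <= len(c) <= 22 for c in cores)


def test_index_includes_21mer():
    seq = "M" + "L" * 20 + "ASA" + "MPMNPADYFSRGTVYIPTRDS" + "R" + "KAQ" + "N" * 10
    cfg = PipelineConfig(signal_mode="provided", signal_provided_map={"m": 24})
    ann = annotate_precursor(PrecursorRecord(id="m", sequence=seq), cfg)
    index = build_candidate_index([ann])
    assert "MPMNPADYFSRGTVYIPTRDS" in {e.peptide.core_sequence
                                       for e in index.entries}


def test_match_exact_peak():
    entry = _entry("QLPGSPWKFWE",
                   (Modification("pyroglutamate", "nterm"),
                    Modification("amidation", "cterm")))
    index = CandidateIndex(entries=[entry])
    peaks = [PeakObservation(mz=678.840405, charge=2)]
    matches = match_peaks(peaks, index, tolerance_ppm=10.0)
    assert len(matches) == 1
    assert matches[0].candidate.core_sequence == "QLPGSPWKFWE"
    assert abs(matches[0].error_ppm) < 1.0


def test_match_empty_inputs():
    index = CandidateIndex(entries=[_entry("ANRYNALR")])
    assert match_peaks([], index) == []
    empty = CandidateIndex(entries=[])
    assert match_peaks([PeakObservation(mz=500.0, charge=1)], empty) == []


def test_decoy_only_match_flagged():
    entry = _entry("ANRYNALR", decoy=True)
    index = CandidateIndex(entries=[entry])
    mz = mass_to_charge(entry.neutral_mass, 2)
    matches = match_peaks([PeakObservation(mz=mz, charge=2)], index)
    assert matches and matches[0].is_decoy


def test_tolerance_monotonicity(toy_annotations):
    index = build_candidate_index(toy_annotations.values())
    peaks = [PeakObservation(mz=mass_to_charge(e.neutral_mass, 2) * (1 + 3e-6),
                             charge=2) for e in index.entries[:20]]
    def keyset(tol):
        return {(m.peak.mz, m.candidate.core_sequence, tuple(m.candidate.mods))
                for m in match_peaks(peaks, index, tol)}
    assert keyset(1.0) <= keyset(5.0) <= keyset(20.0)


def test_charge_consistency():
    """A peak matches identically at any charge carrying the same neutral mass."""
    entry = _entry("GRQPNRNAHYRTLPF", (Modification("amidation", "cterm"),))
    index = CandidateIndex(entries=[entry])
    for z in (1, 2, 3, 5):
        mz = mass_to_charge(entry.neutral_mass, z) * (1 + 2e-6)
        matches = match_peaks([PeakObservation(mz=mz, charge=z)], index, 5.0)
        assert len(matches) == 1
        assert matches[0].error_ppm == pytest.approx(2.0, abs=0.01)


def test_fdr_formula():
    t = [MatchResult(PeakObservation(500.0, 1), _entry("ANRYNALR").peptide,
                     500.0, 0.0, False)] * 90
    d = [MatchResult(PeakObservation(500.0, 1), _entry("ANRYNALR").peptide,
                     500.0, 0.0, True)] * 10
    assert estimate_fdr(t + d).fdr == pytest.approx(10 / 90, abs=1e-9)
    assert estimate_fdr([]).fdr == 0.0
    assert estimate_fdr([]).n_target == 0
    assert estimate_fdr(d).fdr == 1.0           # all-decoy capped at 1


def test_zero_noise_completeness():
    """With no noise and no decoy peaks every true peak is matched correctly
    at 5 ppm and the best-match FDR is zero."""
    cfg = SimConfig(seed=7, noise_sd_ppm=0.0, n_decoy_peaks=0)
    records, truth = generate_precursor_set(cfg)
    peaks, truth = generate_peak_list(truth, cfg)
    matches, fdr, _ = run_search(records, peaks,
                                 PipelineConfig(tolerance_ppm=5.0))
    best = best_matches(matches)
    assert len(best) == len(peaks)               # 100% recall
    assert fdr.fdr == 0.0 and fdr.n_decoy == 0
    planted = {f"{pid}:{p.start}-{p.end}": p.core_sequence
               for pid in truth.precursors
               for p in truth.precursors[pid].peptides}
    for m in best:
        assert not m.is_decoy
        assert m.candidate.core_sequence == planted[m.peak.label]


def test_noise_peaks_produce_spurious_matches():
    """Dense uniform noise eventually hits the index; pooled over seeds the
    decoy-estimated FDR becomes positive."""
    pooled_decoy = pooled_target = spurious = 0
    for seed in range(1, 11):
        cfg = SimConfig(seed=seed, noise_sd_ppm=2.0, n_decoy_peaks=2000)
        records, truth = generate_precursor_set(cfg)
        peaks, truth = generate_peak_list(truth, cfg)
        matches, fdr, _ = run_search(records, peaks, PipelineConfig())
        best = best_matches(matches)
        spurious += sum(1 for m in best if m.peak.label.startswith("noise"))
        pooled_decoy += fdr.n_decoy
        pooled_target += fdr.n_target
    assert spurious > 0
    assert pooled_decoy > 0
    assert 0 < pooled_decoy / pooled_target < 0.2
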