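"""Precursor-mass matching of observed peaks with target-decoy FDR.

Candidates are the mature-peptide variants from annotation, restricted to
the instrument's detectability window (8-22 residues by default: peptides
longer than seven and shorter than twenty-three amino acids).  Each observed
(m/z, charge) peak is matched against every candidate whose theoretical m/z
at that charge lies within a ppm tolerance.  Decoy candidates come from
end-to-end reversed precursors pushed through the identical annotation
path, giving the usual target-decoy FDR estimate n_decoy / n_target.

Matching is precursor-mass only; fragment-ion scoring is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .annotate import PrecursorAnnotation, annotate_precursor
from .config import PipelineConfig
from .io import PeakObservation, PrecursorRecord
from .masses import PROTON, mass_to_charge, peptide_mass
from .ptm import MaturePeptide, Modification


@dataclass(frozen=True)
class IndexEntry:
    peptide: MaturePeptide
    neutral_mass: float
    is_decoy: bool


@dataclass
class CandidateIndex:
    """Mature-peptide variants with neutral monoisotopic masses, mass-sorted."""

    entries: list[IndexEntry]
    min_len: int = 8
    max_len: int = 22

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.neutral_mass)
        self._masses = np.array([e.neutral_mass for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, neutral_mass: float, tolerance_ppm: float) -> list[IndexEntry]:
        """All entries within ``tolerance_ppm`` of a neutral mass."""
        if not len(self.entries):
            return []
        half = neutral_mass * tolerance_ppm * 1e-6
        lo = int(np.searchsorted(self._masses, neutral_mass - half, side="left"))
        hi = int(np.searchsorted(self._masses, neutral_mass + half, side="right"))
        out = []
        for entry in self.entries[lo:hi]:
            # re-check in relative terms against the theoretical mass
            ppm = (neutral_mass - entry.neutral_mass) / entry.neutral_mass * 1e6
            if abs(ppm) <= tolerance_ppm:
                out.append(entry)
        return out


@dataclass(frozen=True)
class MatchResult:
    peak: PeakObservation
    candidate: MaturePeptide
    theo_mz: float
    error_ppm: float
    is_decoy: bool


@dataclass(frozen=True)
class FdrEstimate:
    n_target: int
    n_decoy: int
    fdr: float


def make_decoys(precursors: Iterable[PrecursorRecord]) -> list[PrecursorRecord]:
    """Reverse each precursor end-to-end; ids get a ``DECOY_`` prefix.

    A palindromic sequence yields a decoy equal to its target; that is
    allowed and simply shows up as a shared candidate, flagged as target.
    """
    return [
        PrecursorRecord(id="DECOY_" + rec.id, sequence=rec.sequence[::-1],
                        source_tag="decoy", description=rec.description)
        for rec in precursors
    ]


def build_candidate_index(annotations: Iterable[PrecursorAnnotation],
                          min_len: int = 8, max_len: int = 22,
                          apply_disulfide_mass: bool = False) -> CandidateIndex:
    """Collect mature variants within the length window into a mass index.

    Entries are deduplicated by (core sequence, modification set); when the
    same variant arises from both a target and a decoy precursor the target
    wins, so shared peptides never inflate the decoy count.
    """
    best: dict[tuple, IndexEntry] = {}
    for ann in annotations:
        is_decoy = ann.precursor.id.startswith("DECOY_")
        for pep in ann.mature_peptides:
            if not min_len <= len(pep.core_sequence) <= max_len:
                continue
            mods = list(pep.mods)
            if apply_disulfide_mass:
                n_bridges = pep.core_sequence.count("C") // 2
                mods += [Modification("disulfide", i + 1) for i in range(n_bridges)]
            mass = peptide_mass(pep.core_sequence, mods)
            key = (pep.core_sequence, tuple(sorted(m.name for m in mods)))
            prev = best.get(key)
            if prev is None or (prev.is_decoy and not is_decoy):
                best[key] = IndexEntry(peptide=pep, neutral_mass=mass,
                                       is_decoy=is_decoy)
    return CandidateIndex(entries=list(best.values()),
                          min_len=min_len, max_len=max_len)


def match_peaks(peaks: Sequence[PeakObservation], index: CandidateIndex,
                tolerance_ppm: float = 10.0) -> list[MatchResult]:
    """Match each peak against the index at its own charge.

    For every peak, every candidate whose theoretical m/z at the peak's
    charge lies within the tolerance is returned; results are sorted by
    absolute ppm error (ties by peak order).
    """
    if not tolerance_ppm > 0:
        raise ValueError("tolerance_ppm must be positive")
    results: list[MatchResult] = []
    for peak_i, peak in enumerate(peaks):
        neutral = peak.charge * peak.mz - peak.charge * PROTON
        for entry in index.lookup(neutral, tolerance_ppm):
            theo_mz = mass_to_charge(entry.neutral_mass, peak.charge)
            error_ppm = (peak.mz - theo_mz) / theo_mz * 1e6
            results.append(MatchResult(peak=peak, candidate=entry.peptide,
                                       theo_mz=theo_mz, error_ppm=error_ppm,
                                       is_decoy=entry.is_decoy))
    results.sort(key=lambda m: abs(m.error_ppm))
    return results


def best_matches(matches: Sequence[MatchResult]) -> list[MatchResult]:
    """One best assignment per peak: smallest |ppm error|, ties favor target.

    Reversal preserves amino-acid composition, so a reversed-decoy peptide
    can tie its target exactly at the precursor-mass level; as in standard
    target-decoy scoring, such ties are awarded to the target.
    """
    best: dict[tuple[float, int, str], MatchResult] = {}
    for m in matches:
        key = (m.peak.mz, m.peak.charge, m.peak.label)
        cur = best.get(key)
        if cur is None:
            best[key] = m
            continue
        # near-ties (below summation round-off, ~1e-6 ppm) go to the target
        diff = abs(m.error_ppm) - abs(cur.error_ppm)
        if diff < -1e-6 or (abs(diff) <= 1e-6 and cur.is_decoy and not m.is_decoy):
            best[key] = m
    return sorted(best.values(), key=lambda m: abs(m.error_ppm))


def estimate_fdr(matches: Sequence[MatchResult]) -> FdrEstimate:
    """Target-decoy FDR: min(1, n_decoy / max(1, n_target))."""
    n_decoy = sum(1 for m in matches if m.is_decoy)
    n_target = len(matches) - n_decoy
    fdr = 0.0 if (n_target == 0 and n_decoy == 0) else min(
        1.0, n_decoy / max(1, n_target))
    return FdrEstimate(n_target=n_target, n_decoy=n_decoy, fdr=fdr)


def run_search(targets: Sequence[PrecursorRecord],
               peaks: Sequence[PeakObservation],
               config: PipelineConfig | None = None,
               with_decoys: bool = True
               ) -> tuple[list[MatchResult], FdrEstimate, CandidateIndex]:
    """Annotate targets (and reversed decoys), build the index, match peaks."""
    config = config or PipelineConfig()
    records = list(targets)
    if with_decoys:
        records = records + make_decoys(targets)
    provided = config.signal_provided_map
    annotations = []
    for rec in records:
        end = None
        if config.signal_mode == "provided" and rec.id.startswith("DECOY_"):
            # decoys carry no signal annotation of their own; process them
            # with the same boundary as their target so the paths match
            end = provided.get(rec.id, provided.get(rec.id[len("DECOY_"):]))
        annotations.append(annotate_precursor(rec, config, provided_signal_end=end))
    index = build_candidate_index(
        annotations, config.min_peptide_len, config.max_peptide_len,
        config.apply_disulfide_mass)
    matches = match_peaks(peaks, index, config.tolerance_ppm)
    return matches, estimate_fdr(best_matches(matches)), index
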