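"""Precursor annotation: signal region, cleavage sites, peptide excision.

A neuropeptide precursor (prepropeptide) is read N- to C-terminal as a
signal peptide, then peptide cassettes flanked by basic cleavage sites,
interspersed with acidic spacer segments.  Prohormone convertases cut
C-terminal to runs of 1-3 Lys/Arg residues; carboxypeptidase then trims the
exposed basic residues, so basic-run residues belong to no mature peptide.
All coordinates in this module are 1-based inclusive.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .config import PipelineConfig
from .io import PrecursorRecord, validate_sequence
from . import ptm

#: Small residues accepted at the (-3, -1) positions of a signal-peptidase site.
SMALL_RESIDUES = frozenset("AGSCTV")
BASIC = frozenset("KR")
ACIDIC = frozenset("DE")

SITE_KINDS = {1: "monobasic", 2: "dibasic", 3: "tribasic"}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class SignalRegion:
    """N-terminal signal peptide: ``end`` is the last signal residue (1-based)."""

    end: int
    mode: str                 # "provided" | "heuristic"
    score: float | None = None

    def __post_init__(self) -> None:
        if not 10 <= self.end <= 45:
            raise AnnotationError(
                f"signal end {self.end} outside plausible range [10, 45]")


@dataclass(frozen=True)
class CleavageSite:
    """A located basic-residue run; cleavage occurs after ``end``."""

    start: int
    end: int
    kind: str
    residues: str

    def __post_init__(self) -> None:
        if set(self.residues) - BASIC:
            raise AnnotationError(f"site residues must be K/R: {self.residues!r}")
        if len(self.residues) != self.end - self.start + 1:
            raise AnnotationError("site span does not match residue run")

    @property
    def boundary(self) -> int:
        return self.end


@dataclass(frozen=True)
class Segment:
    """A maximal stretch between signal end, site spans and precursor end."""

    precursor_id: str
    start: int
    end: int
    sequence: str
    n_term_context: str       # "signal" | "cleavage_site" | "precursor_end"
    c_term_context: str


@dataclass(frozen=True)
class SegmentClass:
    label: str                # "bioactive_candidate" | "acidic_spacer" | "unassigned"
    acidic_count: int
    acidic_fraction: float


@dataclass
class PrecursorAnnotation:
    """Full annotation of one precursor, serializable as the report TSV."""

    precursor: PrecursorRecord
    signal: SignalRegion | None
    sites: list[CleavageSite]
    segments: list[Segment]
    segment_classes: list[SegmentClass]
    mature_peptides: list["ptm.MaturePeptide"]
    candidate_precursor: bool
    copy_counts: dict[str, int] = field(default_factory=dict)


def hydropathy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy of a residue stretch."""
    if not sequence:
        return 0.0
    return sum(KYTE_DOOLITTLE[ch] for ch in sequence) / len(sequence)


def predict_signal_region(sequence: str, mode: str = "heuristic",
                          provided_end: int | None = None) -> SignalRegion:
    """Locate the signal-peptide boundary.

    ``provided`` mode echoes an externally computed boundary.  ``heuristic``
    mode scores every candidate cut position c in [15, 35]: the mean
    hydropathy of the hydrophobic core (residues 5..c-6) plus one point for
    a small residue at each of positions c-2 and c (the classic (-3, -1)
    rule of signal peptidase, relative to the cut after c).  Ties break
    toward the smaller c.
    """
    if mode == "provided":
        if provided_end is None:
            raise AnnotationError("provided mode requires provided_end")
        if provided_end >= len(sequence):
            raise AnnotationError(
                f"provided signal end {provided_end} >= precursor length "
                f"{len(sequence)}")
        return SignalRegion(end=provided_end, mode="provided")
    if mode != "heuristic":
        raise AnnotationError(f"unknown signal mode {mode!r}")
    if len(sequence) < 30:
        raise AnnotationError(
            f"sequence of {len(sequence)} residues is too short for signal "
            "prediction (need >= 30)")
    best_c, best_score = None, None
    for c in range(15, min(35, len(sequence) - 1) + 1):
        core = sequence[4:c - 6]          # residues 5..c-6, 1-based
        score = hydropathy(core)
        if sequence[c - 3] in SMALL_RESIDUES:   # position c-2
            score += 1.0
        if sequence[c - 1] in SMALL_RESIDUES:   # position c
            score += 1.0
        if best_score is None or score > best_score:
            best_c, best_score = c, score
    return SignalRegion(end=best_c, mode="heuristic", score=best_score)


def _monobasic_ok_strict(sequence: str, i: int) -> bool:
    """Veenstra-style consensus for a lone K/R at 0-based index ``i``."""
    if i + 1 < len(sequence) and sequence[i + 1] == "P":
        return False
    return any(i - off >= 0 and sequence[i - off] in BASIC for off in (3, 5, 7))


def find_cleavage_sites(sequence: str, monobasic_mode: str = "strict",
                        offset: int = 0) -> list[CleavageSite]:
    """Locate mono-/di-/tribasic convertase sites in ``sequence``.

    Every maximal K/R run of length >= 2 is a site (a run of 4+ is reported
    as a single site spanning the whole run, kind ``tribasic``).  A single
    K or R is a monobasic site iff it is not immediately followed by P and
    another basic residue lies at relative position -3, -5 or -7; in
    ``permissive`` mode any single R not followed by P also qualifies.
    ``offset`` excludes the first ``offset`` residues (the signal region)
    from the search; upstream-context positions inside the excluded region
    are not consulted.  Coordinates refer to the full sequence, 1-based.
    """
    if monobasic_mode not in ("strict", "permissive", "off"):
        raise AnnotationError(f"unknown monobasic mode {monobasic_mode!r}")
    region = sequence[offset:]
    sites: list[CleavageSite] = []
    i = 0
    n = len(region)
    while i < n:
        if region[i] not in BASIC:
            i += 1
            continue
        j = i
        while j < n and region[j] in BASIC:
            j += 1
        run = region[i:j]
        if len(run) >= 2:
            kind = SITE_KINDS[min(len(run), 3)]
            sites.append(CleavageSite(start=offset + i + 1, end=offset + j,
                                      kind=kind, residues=run))
        elif monobasic_mode != "off":
            accept = _monobasic_ok_strict(region, i)
            if not accept and monobasic_mode == "permissive":
                followed_by_p = i + 1 < n and region[i + 1] == "P"
                accept = run == "R" and not followed_by_p
            if accept:
                sites.append(CleavageSite(start=offset + i + 1, end=offset + j,
                                          kind="monobasic", residues=run))
        i = j
    return sites


def excise_peptides(precursor: PrecursorRecord, signal: SignalRegion | None,
                    sites: Sequence[CleavageSite]) -> list[Segment]:
    """Cut the precursor into maximal non-site stretches after the signal.

    Basic-run residues belong to no segment; zero-length stretches between
    adjacent sites are dropped.  Together with the signal and the sites the
    segments partition the precursor exactly.
    """
    seq = precursor.sequence
    signal_end = signal.end if signal is not None else 0
    if signal_end >= len(seq):
        raise AnnotationError(
            f"signal end {signal_end} >= precursor length {len(seq)}")
    ordered = sorted(sites, key=lambda s: s.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start <= prev.end:
            raise AnnotationError("overlapping cleavage sites")
    if ordered and ordered[0].start <= signal_end:
        raise AnnotationError("cleavage site inside the signal region")
    segments: list[Segment] = []
    cursor = signal_end + 1
    left_context = "signal" if signal is not None else "precursor_end"
    for site in ordered:
        if site.start > cursor:
            segments.append(Segment(
                precursor_id=precursor.id, start=cursor, end=site.start - 1,
                sequence=seq[cursor - 1:site.start - 1],
                n_term_context=left_context, c_term_context="cleavage_site"))
        cursor = site.end + 1
        left_context = "cleavage_site"
    if cursor <= len(seq):
        segments.append(Segment(
            precursor_id=precursor.id, start=cursor, end=len(seq),
            sequence=seq[cursor - 1:],
            n_term_context=left_context, c_term_context="precursor_end"))
    return segments


def classify_segment(segment: Segment, min_acidic: int = 3,
                     min_fraction: float = 0.25) -> SegmentClass:
    """Label a segment as acidic spacer, bioactive candidate or unassigned.

    Asp/Glu-rich stretches separating peptide copies are presumed
    non-bioactive spacer material; the thresholds (>= ``min_acidic`` D/E
    residues and >= ``min_fraction`` of the length) are configurable.
    Segments shorter than 3 residues are left unassigned.
    """
    n = len(segment.sequence)
    acidic = sum(1 for ch in segment.sequence if ch in ACIDIC)
    fraction = acidic / n if n else 0.0
    if n < 3:
        label = "unassigned"
    elif acidic >= min_acidic and fraction >= min_fraction:
        label = "acidic_spacer"
    else:
        label = "bioactive_candidate"
    return SegmentClass(label=label, acidic_count=acidic, acidic_fraction=fraction)


def count_copies(peptides: Iterable) -> dict[str, int]:
    """Count identical mature sequences (amidated forms counted separately).

    Accepts plain residue strings or :class:`~holopept.ptm.MaturePeptide`
    objects; for the latter the key is the core sequence with an ``-NH2``
    suffix when amidated, so amidated and unamidated forms of the same core
    are distinct.
    """
    counts: Counter[str] = Counter()
    for pep in peptides:
        if isinstance(pep, str):
            key = pep
        else:
            key = pep.core_sequence + ("-NH2" if pep.amidated else "")
        counts[key] += 1
    return dict(counts)


def annotate_precursor(precursor: PrecursorRecord,
                       config: PipelineConfig | None = None,
                       provided_signal_end: int | None = None) -> PrecursorAnnotation:
    """Run the full per-precursor annotation.

    Composes signal prediction, cleavage-site detection (restricted to the
    post-signal region), excision, classification and PTM variant
    derivation.  A precursor is flagged ``candidate_precursor`` iff it has a
    signal region and at least one bioactive-candidate segment — the same
    screen used by de novo precursor-discovery tools (signal peptide plus
    dibasic cleavage sites).
    """
    config = config or PipelineConfig()
    signal: SignalRegion | None
    if config.signal_mode == "provided":
        end = provided_signal_end
        if end is None:
            end = config.signal_provided_map.get(precursor.id)
        if end is None:
            raise AnnotationError(
                f"no provided signal boundary for {precursor.id!r}")
        signal = predict_signal_region(precursor.sequence, "provided", end)
    else:
        try:
            signal = predict_signal_region(precursor.sequence, "heuristic")
        except AnnotationError:
            signal = None      # too short to carry a signal peptide
    offset = signal.end if signal is not None else 0
    sites = find_cleavage_sites(precursor.sequence, config.monobasic_mode,
                                offset=offset)
    segments = excise_peptides(precursor, signal, sites)
    classes = [classify_segment(s, config.spacer_min_acidic,
                                config.spacer_min_fraction) for s in segments]
    limits = ptm.VariantLimits(
        max_oxidations=config.max_oxidations,
        max_deamidations=config.max_deamidations,
        max_total_variants=config.max_total_variants)
    peptides: list[ptm.MaturePeptide] = []
    for seg in segments:
        peptides.extend(ptm.derive_mature_variants(seg, limits))
    # de novo screen: a signal peptide AND at least one cleavage-site-bounded
    # bioactive-candidate segment (a signal alone is not enough)
    candidate = signal is not None and bool(sites) and any(
        cls.label == "bioactive_candidate"
        and "cleavage_site" in (seg.n_term_context, seg.c_term_context)
        for seg, cls in zip(segments, classes))
    base_forms = [p for p in peptides if not p.mods or
                  (p.amidated and len(p.mods) == 1)]
    return PrecursorAnnotation(
        precursor=precursor, signal=signal, sites=sites, segments=segments,
        segment_classes=classes, mature_peptides=peptides,
        candidate_precursor=candidate,
        copy_counts=count_copies(base_forms))
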