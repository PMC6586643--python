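"""Gene-structure arithmetic for precursor coding sequences.

Given the ordered protein-coding exon lengths of a precursor CDS, compute
the phase of each intron (0 = between codons, 1/2 = inside a codon) and
which residue(s) it interrupts: a phase-1/2 intron falls inside one codon
and interrupts that single residue; a phase-0 intron falls between codons
and is reported with the two flanking residues.  Spliced alignment itself
is not performed here — exon lengths are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


class GeneStructureError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    precursor_id: str
    exon_lengths: tuple[int, ...]       # nucleotides, protein-coding portions
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.exon_lengths:
            raise GeneStructureError("gene model needs at least one exon")
        if any(n < 1 for n in self.exon_lengths):
            raise GeneStructureError("exon lengths must be positive")


@dataclass(frozen=True)
class IntronAnnotation:
    junction_index: int                  # 1-based inter-exon boundary
    phase: int                           # 0 | 1 | 2
    interrupted_residues: tuple[int, ...]  # one residue (phase 1/2) or two (phase 0)


def codon_interruptions(model: GeneModel) -> list[IntronAnnotation]:
    """Phase and interrupted residue(s) for every inter-exon junction."""
    total = sum(model.exon_lengths)
    if total % 3 != 0 and not model.partial:
        raise GeneStructureError(
            f"{model.precursor_id}: CDS length {total} not divisible by 3 "
            "(set partial=True for incomplete models)")
    annotations: list[IntronAnnotation] = []
    cum = 0
    for junction, length in enumerate(model.exon_lengths[:-1], start=1):
        cum += length
        phase = cum % 3
        if phase == 0:
            residues = (cum // 3, cum // 3 + 1)
        else:
            residues = (cum // 3 + 1,)
        annotations.append(IntronAnnotation(junction_index=junction,
                                            phase=phase,
                                            interrupted_residues=residues))
    return annotations


def splice_variants(transcript_a: Sequence[int], transcript_b: Sequence[int],
                    catalogue: Sequence[int] | None = None
                    ) -> dict[str, set[int]]:
    """Shared and transcript-exclusive exon usage for two splice isoforms.

    Exon ids must come from one gene's exon catalogue (``catalogue`` when
    given, else the union of the two lists defines it); ids must not repeat
    within a transcript.
    """
    a, b = list(transcript_a), list(transcript_b)
    for name, ids in (("first", a), ("second", b)):
        if len(set(ids)) != len(ids):
            raise GeneStructureError(f"{name} transcript repeats an exon id")
        if any(not isinstance(i, int) or i < 1 for i in ids):
            raise GeneStructureError(f"{name} transcript has an invalid exon id")
    if catalogue is not None:
        unknown = (set(a) | set(b)) - set(catalogue)
        if unknown:
            raise GeneStructureError(
                f"unknown exon id(s): {sorted(unknown)}")
    set_a, set_b = set(a), set(b)
    return {
        "shared": set_a & set_b,
        "exclusive_to_first": set_a - set_b,
        "exclusive_to_second": set_b - set_a,
    }
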