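"""Post-translational modification rules for mature-peptide variants.

From each excised segment the engine enumerates the modified forms a
peptidomic search would consider: C-terminal amidation of a segment-terminal
Gly (the Gly is consumed: peptidylglycine alpha-amidating monooxygenase
converts ...X-Gly to ...X-NH2), N-terminal Gln cyclization to pyroglutamate,
methionine oxidation and asparagine deamidation.  Because mature peptides
detected without their terminal Gly and without an amide do occur
(carboxypeptidase trimming, or atypical processing), the Gly-trimmed
unamidated form is emitted alongside the Gly-retained and amidated forms.

Disulfide bridges are annotated as a capacity (pairs of cysteines) but are
not applied as mass deltas unless explicitly enabled; tyrosine sulfation is
flagged (presence of Tyr) and never given a mass variant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from .masses import MOD_DELTAS_MONO, NH3_MONO, WATER_MONO

if TYPE_CHECKING:          # avoid a circular import; Segment is duck-typed
    from .annotate import Segment

#: Net monoisotopic delta of "drop terminal G, add NH3" relative to the
#: Gly-retained free acid.
AMIDATION_NET_DELTA = -(57.021464 + WATER_MONO) + NH3_MONO   # -58.005480


@dataclass(frozen=True, order=True)
class Modification:
    """A named modification at a residue index (1-based in the core) or terminus."""

    name: str
    site: int | str = "cterm"

    @property
    def mass_delta(self) -> float:
        if self.name == "amidation":
            return AMIDATION_NET_DELTA
        return MOD_DELTAS_MONO[self.name]


@dataclass(frozen=True)
class MaturePeptide:
    """An excised peptide with one concrete modification set applied."""

    core_sequence: str
    mods: tuple[Modification, ...]
    precursor_id: str
    start: int
    end: int
    amidated: bool = False
    sulfation_candidate: bool = False

    @property
    def provenance(self) -> tuple[str, int, int]:
        return (self.precursor_id, self.start, self.end)

    def __str__(self) -> str:
        return self.core_sequence + ("-NH2" if self.amidated else "")


@dataclass(frozen=True)
class VariantLimits:
    max_oxidations: int = 1
    max_deamidations: int = 1
    max_total_variants: int = 16


def disulfide_capacity(sequence: str) -> int:
    """Maximum number of intramolecular disulfide bridges: floor(#Cys / 2)."""
    return sequence.count("C") // 2


def _site_combinations(positions: list[int], max_n: int):
    """All subsets of up to ``max_n`` sites, smallest first, in site order."""
    for n in range(0, max_n + 1):
        yield from itertools.combinations(positions, n)


def derive_mature_variants(segment: "Segment",
                           limits: VariantLimits | None = None
                           ) -> list[MaturePeptide]:
    """Enumerate the mature-peptide variants of one excised segment.

    The unmodified Gly-retained base form is always first.  If the segment
    ends in Gly and abuts a cleavage site or the precursor end, the
    des-Gly amidated and des-Gly unamidated forms are added.  Each terminal
    form is then expanded with pyroglutamate (N-terminal Q only) and with up
    to ``max_oxidations`` Met oxidations and ``max_deamidations`` Asn
    deamidations.  Enumeration is deterministic (fewest modifications first,
    then site order) and truncated at ``max_total_variants``.
    """
    limits = limits or VariantLimits()
    seq = segment.sequence
    if not seq:
        return []

    # (core, terminal mods, amidated?) terminal forms, base form first
    terminal_forms: list[tuple[str, tuple[Modification, ...], bool]] = [
        (seq, (), False)]
    amidatable = (seq.endswith("G") and len(seq) > 1 and
                  segment.c_term_context in ("cleavage_site", "precursor_end"))
    if amidatable:
        core = seq[:-1]
        terminal_forms.append((core, (Modification("amidation", "cterm"),), True))
        terminal_forms.append((core, (), False))   # Gly-trimmed, unamidated

    candidates: list[tuple[tuple, MaturePeptide]] = []
    for form_rank, (core, term_mods, amidated) in enumerate(terminal_forms):
        pyro_options: list[tuple[Modification, ...]] = [()]
        if core.startswith("Q"):
            pyro_options.append((Modification("pyroglutamate", "nterm"),))
        met_sites = [i + 1 for i, ch in enumerate(core) if ch == "M"]
        asn_sites = [i + 1 for i, ch in enumerate(core) if ch == "N"]
        for pyro in pyro_options:
            for ox in _site_combinations(met_sites, limits.max_oxidations):
                for deam in _site_combinations(asn_sites, limits.max_deamidations):
                    mods = term_mods + pyro
                    mods += tuple(Modification("oxidation_M", i) for i in ox)
                    mods += tuple(Modification("deamidation_N", i) for i in deam)
                    pep = MaturePeptide(
                        core_sequence=core, mods=mods,
                        precursor_id=segment.precursor_id,
                        start=segment.start, end=segment.end,
                        amidated=amidated,
                        sulfation_candidate="Y" in core)
                    key = (len(mods), form_rank, len(pyro) == 0, ox, deam)
                    candidates.append((key, pep))
    candidates.sort(key=lambda item: item[0])
    return [pep for _, pep in candidates[:limits.max_total_variants]]
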