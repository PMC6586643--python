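"""Peptide mass and m/z arithmetic.

Neutral free-acid mass is the sum of residue masses plus one water; a
C-terminally amidated peptide replaces the water with NH3 (net −0.984016 Da
monoisotopic relative to the free acid of the same core).  All other
modifications are fixed additive deltas:

=================  ===========================  ==============
modification       chemistry                    mono delta (Da)
=================  ===========================  ==============
pyroglutamate      N-terminal Gln − NH3         −17.026549
oxidation_M        Met + O                      +15.994915
deamidation_N      Asn → Asp (−NH +O)           +0.984016
disulfide          −2 H per bridge              −2.015650
=================  ===========================  ==============

m/z for a z-fold protonated ion is (M + z·m_p)/z with the proton mass
m_p = 1.00727646 Da (the proton, not the hydrogen atom — required to
reproduce published Orbitrap m/z values).

:func:`elemental_oracle_mass` recomputes the same quantity from per-residue
elemental compositions via pyteomics and shares no code or constants with
:func:`peptide_mass`; it exists purely as an independent verification path.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

PROTON = 1.00727646
WATER_MONO = 18.010565
NH3_MONO = 17.026549
WATER_AVG = 18.01528
NH3_AVG = 17.03052

#: Monoisotopic residue masses (Da), standard values.
MONO = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: Average (chemical) residue masses (Da).
AVERAGE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

MOD_DELTAS_MONO = {
    "pyroglutamate": -NH3_MONO,
    "oxidation_M": +15.994915,
    "deamidation_N": +0.984016,
    "disulfide": -2.015650,
}

MOD_DELTAS_AVG = {
    "pyroglutamate": -NH3_AVG,
    "oxidation_M": +15.9994,
    "deamidation_N": +0.9848,
    "disulfide": -2.0159,
}


class MassError(ValueError):
    """Raised for invalid sequences or modification/sequence mismatches."""


def _mod_names(mods: Iterable) -> list[str]:
    names = []
    for mod in mods or ():
        names.append(mod if isinstance(mod, str) else mod.name)
    return names


def _validate(core_sequence: str, names: list[str]) -> None:
    if not core_sequence:
        raise MassError("empty sequence")
    for pos, ch in enumerate(core_sequence, start=1):
        if ch not in MONO:
            raise MassError(f"illegal residue {ch!r} at position {pos}")
    counts = Counter(names)
    known = set(MOD_DELTAS_MONO) | {"amidation"}
    for name in counts:
        if name not in known:
            raise MassError(f"unknown modification {name!r}")
    if counts["amidation"] > 1:
        raise MassError("amidation: at most one C-terminal amide")
    if counts["pyroglutamate"]:
        if counts["pyroglutamate"] > 1 or core_sequence[0] != "Q":
            raise MassError("pyroglutamate: requires a single N-terminal Q")
    if counts["oxidation_M"] > core_sequence.count("M"):
        raise MassError("oxidation_M: more oxidations than methionines")
    if counts["deamidation_N"] > core_sequence.count("N"):
        raise MassError("deamidation_N: more deamidations than asparagines")
    if counts["disulfide"] > core_sequence.count("C") // 2:
        raise MassError("disulfide: more bridges than cysteine pairs")


def peptide_mass(core_sequence: str, mods: Iterable = (),
                 kind: str = "monoisotopic") -> float:
    """Neutral mass (Da) of a peptide with the given modification set.

    ``core_sequence`` is the residue string *after* any terminal-Gly removal;
    an ``amidation`` entry in ``mods`` means the C-terminus is -NH2 rather
    than -OH.  ``kind`` selects monoisotopic or average residue masses.
    """
    names = _mod_names(mods)
    _validate(core_sequence, names)
    if kind == "monoisotopic":
        table, water, nh3, deltas = MONO, WATER_MONO, NH3_MONO, MOD_DELTAS_MONO
    elif kind == "average":
        table, water, nh3, deltas = AVERAGE, WATER_AVG, NH3_AVG, MOD_DELTAS_AVG
    else:
        raise MassError(f"unknown mass kind {kind!r}")
    mass = sum(table[ch] for ch in core_sequence)
    mass += nh3 if "amidation" in names else water
    for name in names:
        if name != "amidation":
            mass += deltas[name]
    return mass


def mass_to_charge(neutral_mass: float, charge: int) -> float:
    """m/z (thomson) of the z-fold protonated ion of a neutral mass."""
    charge = int(charge)
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def charge_to_neutral(mz: float, charge: int) -> float:
    """Neutral mass recovered from an observed m/z and charge."""
    charge = int(charge)
    if charge < 1:
        raise MassError(f"charge must be >= 1, got {charge}")
    return charge * mz - charge * PROTON


def elemental_oracle_mass(core_sequence: str, mods: Iterable = ()) -> float:
    """Monoisotopic mass recomputed from elemental composition (pyteomics).

    Builds the peptide's C/H/N/O/S composition and applies each modification
    as a composition change, then sums isotope masses.  Independent of
    :func:`peptide_mass` by construction.
    """
    from pyteomics.mass import Composition

    names = _mod_names(mods)
    _validate(core_sequence, names)
    comp = Composition(sequence=core_sequence)
    for name in names:
        if name == "amidation":          # -OH +NH2 at the C-terminus
            comp["O"] -= 1
            comp["N"] += 1
            comp["H"] += 1
        elif name == "pyroglutamate":    # cyclization, loss of NH3
            comp["N"] -= 1
            comp["H"] -= 3
        elif name == "oxidation_M":
            comp["O"] += 1
        elif name == "deamidation_N":    # Asn -> Asp
            comp["N"] -= 1
            comp["H"] -= 1
            comp["O"] += 1
        elif name == "disulfide":
            comp["H"] -= 2
    return comp.mass()
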