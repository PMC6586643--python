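"""Published reference peptides from the *Apostichopus japonicus* CNR peptidome.

These are the neuropeptides detected by LC-MS/MS in circumoral nerve ring
(CNR) extracts of the sea cucumber *A. japonicus*, with their published
observed m/z, charge and predicted monoisotopic mass.  They serve as the
package's numeric ground truth: the mass arithmetic must reproduce every
published value at its printed precision.

Notes on individual entries:

* ``mass_checked`` marks entries whose published m/z and mass are printed to
  full (>= 5 decimal) precision and agree with exact monoisotopic
  computation; these anchor the numeric acceptance tests.
* APLADDTAHQVDE is published only to two decimals (691.32 / 1380.62).
* The published APHAIRPPSG entry (473.266876 / 944.519199) matches the
  9-mer APHAIRPPS free acid rather than the full 10-mer (1001.540635);
  the discrepancy is unexplained in the source data, so the entry is kept
  for reference but excluded from numeric checks (``anomalous=True``).
* "Acylamide" in the published modification strings denotes the C-terminal
  amide; the masses confirm this reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ptm import Modification

AMIDE = Modification("amidation", "cterm")
PYROGLU = Modification("pyroglutamate", "nterm")


def _ox(site: int) -> Modification:
    return Modification("oxidation_M", site)


@dataclass(frozen=True)
class ReferencePeptide:
    name: str
    core_sequence: str                  # mature core (terminal Gly removed if amidated)
    mods: tuple[Modification, ...]
    mz: float                           # published observed m/z
    charge: int
    mono_mass: float                    # published predicted mass (Da)
    precursor: str = ""
    mass_checked: bool = True
    anomalous: bool = False


#: Detected CNR peptides with published m/z / charge / mass.
REFERENCE_PEPTIDES: tuple[ReferencePeptide, ...] = (
    ReferencePeptide("AjTRH7", "QLPGSPWKFWE", (PYROGLU, AMIDE),
                     678.840405, 2, 1355.666264, "AjTRHP"),
    ReferencePeptide("AjKP1", "GRQPNRNAHYRTLPF", (AMIDE,),
                     609.327549, 3, 1824.96082, "AjKPP"),
    ReferencePeptide("AjPPLN2a", "FGNSNMDPLVHSLIG", (_ox(6), AMIDE),
                     808.398489, 2, 1614.782432, "AjPPLNP2"),
    ReferencePeptide("AjPPLN2b", "FGSSQIMDPLRYSLVS", (_ox(7), AMIDE),
                     907.958911, 2, 1813.90327, "AjPPLNP2"),
    ReferencePeptide("AjPPLN2c", "FGNSNMDPLMYSMIG", (AMIDE,),
                     838.367486, 2, 1674.72042, "AjPPLNP2"),
    ReferencePeptide("AjL-SALMFa", "RMGFTGNTGILL", (AMIDE,),
                     639.85299, 2, 1277.69143, "AjL-SALMFaP"),
    ReferencePeptide("AjANP", "ANRYNALR", (),
                     489.267407, 2, 976.520262, "AjANPP"),
    ReferencePeptide("Ajn23-spacer", "APLADDTAHQVDE", (),
                     691.32, 2, 1380.62, "Ajnp23", mass_checked=False),
    ReferencePeptide("AjGN19-b", "GQMMMRDMDLLEESL", (),
                     899.89575, 2, 1797.77695, "AjGN19P"),
    ReferencePeptide("AjGN19", "GGRLPNYAGPPRMPWLIHN", (),
                     716.04242, 3, 2145.10543, "AjGN19P"),
    ReferencePeptide("AjSWYG-3", "SWYGSLASALL", (AMIDE,),
                     583.813856, 2, 1165.61316, "AjSWYGP-3"),
    ReferencePeptide("AjAPHAIRPPSG", "APHAIRPPSG", (),
                     473.266876, 2, 944.519199, "AjAPHAIRPPSGP",
                     mass_checked=False, anomalous=True),
    ReferencePeptide("AjMPMN", "MPMNPADYFSRGTVYIPTRDS", (_ox(1),),
                     812.043715, 3, 2433.109329, "AjMPMNP"),
)


def checked_peptides() -> list[ReferencePeptide]:
    """The entries printed to full precision, used for numeric validation."""
    return [p for p in REFERENCE_PEPTIDES if p.mass_checked]


# ---------------------------------------------------------------------------
# Synthetic precursor fragments for structure tests.
#
# Full precursor sequences are not published in plain text, so these toys
# embed the published mature-peptide regions (with their published signal
# boundaries in SIGNAL_ENDS) in synthetic signal/tail scaffolding.  They are
# synthetic constructs, not deposited sequences.
# ---------------------------------------------------------------------------

_SIG21 = "MKLLVLLALFAVALVAASSSA"          # 21-residue synthetic signal
_SIG24 = "MKTLAVLLVLFALAVSSIAVLAEA"       # 24-residue synthetic signal
_TAIL = "SNDPETNQHAGSTDEQNSPATHGSDE"      # inert polar tail, no K/R


@dataclass(frozen=True)
class ToyPrecursor:
    sequence: str
    signal_end: int
    #: monobasic detection mode matching the published site annotation of the
    #: precursor the toy mimics ("off" where only dibasic sites were marked:
    #: kisspeptin-type peptides contain internal arginines that a blanket
    #: monobasic consensus would over-call, yet the intact peptide was
    #: detected by MS).
    monobasic_mode: str = "strict"


TOY_PRECURSORS: dict[str, ToyPrecursor] = {
    # 24-residue signal, vasopressin/oxytocin-type nonapeptide + Gly + KR +
    # neurophysin-like tail (holotocin layout)
    "holotocin_toy": ToyPrecursor(_SIG24 + "CFITNCPLGG" + "KR" + _TAIL, 24),
    # TRH-type cassette: pyroGlu + amide 11-mer flanked by dibasic sites
    "trh7_toy": ToyPrecursor(
        _SIG24 + "EDDSAEN" + "KR" + "QLPGSPWKFWEG" + "KR" + _TAIL, 24),
    # kisspeptin-type: RR then the amidated 15-mer + Gly, then KR
    "kp1_toy": ToyPrecursor(
        _SIG24 + "SDEAQTE" + "RR" + "GRQPNRNAHYRTLPFG" + "KR" + _TAIL, 24,
        monobasic_mode="off"),
    # 21-residue signal, Gly-retained 10-mer bounded C-terminally by a
    # monobasic R with an upstream basic residue satisfying the consensus
    "aphairppsg_toy": ToyPrecursor(_SIG21 + "APHAIRPPSG" + "R" + _TAIL, 21),
}

SIGNAL_ENDS: dict[str, int] = {k: t.signal_end for k, t in TOY_PRECURSORS.items()}
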