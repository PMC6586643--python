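"""Synthetic prepropeptides and peak lists with known ground truth.

Each simulated precursor mirrors the architecture the annotation engine
assumes: an N-terminal signal peptide (Met + a hydrophobic core drawn from
L/V/I/A/F, ending in the small-residue (-3,-1) signal-peptidase motif), a
leading acidic spacer, and then dibasic(KR)-flanked peptide cassettes —
optionally Gly-terminated for amidation, optionally repeated — interleaved
with further acidic spacers.  Peptide bodies are drawn from the 18 non-K/R
residues so the planted cleavage sites are unambiguous; a flag re-admits
internal K/R to stress-test the monobasic rule.

The peak generator emits one peak per planted peptide inside the
detectability window, at the theoretical m/z of its intended mature form
perturbed by Gaussian ppm noise, plus uniform decoy/noise peaks.  All
randomness flows through one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeakObservation, PrecursorRecord
from .masses import mass_to_charge, peptide_mass
from .ptm import Modification

HYDROPHOBIC = "LVIAF"
SMALL = "AGS"
#: Residues for peptide bodies: the 20 standard minus K and R.
NON_BASIC = "ACDEFGHILMNPQSTVWY"
ACIDIC_POOL = "DDEEAGSTPN"    # >= 30% D/E guaranteed by construction below


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_precursors: int = 20
    cassettes_per_precursor: tuple[int, int] = (1, 3)
    copy_number_range: tuple[int, int] = (1, 3)
    signal_length_range: tuple[int, int] = (15, 35)
    p_terminal_gly: float = 0.6
    p_acidic_spacer: float = 0.5
    peptide_length_range: tuple[int, int] = (5, 25)
    spacer_length_range: tuple[int, int] = (8, 16)
    noise_sd_ppm: float = 2.0
    n_decoy_peaks: int = 20
    allow_internal_basic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cassettes_per_precursor", "copy_number_range",
                     "signal_length_range", "peptide_length_range",
                     "spacer_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise SimulationError(f"empty or invalid range for {name}")
        if self.peptide_length_range[0] < 1:
            raise SimulationError("peptides must have positive length")
        for name in ("p_terminal_gly", "p_acidic_spacer"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"{name} must be a probability")
        if self.noise_sd_ppm < 0:
            raise SimulationError("noise_sd_ppm must be >= 0")
        if self.signal_length_range[0] < 10 or self.signal_length_range[1] > 45:
            raise SimulationError("signal lengths must stay within [10, 45]")


@dataclass(frozen=True)
class PlantedPeptide:
    precursor_id: str
    start: int                  # 1-based inclusive within the precursor
    end: int
    sequence: str               # as planted, including any terminal Gly
    amidated: bool              # intended mature form carries a C-terminal amide

    @property
    def core_sequence(self) -> str:
        return self.sequence[:-1] if self.amidated else self.sequence

    @property
    def mods(self) -> tuple[Modification, ...]:
        return ((Modification("amidation", "cterm"),) if self.amidated else ())


@dataclass(frozen=True)
class PeakTruth:
    mz: float
    charge: int
    source: str                 # planted-peptide label or "noise"


@dataclass
class PrecursorTruth:
    signal_end: int
    site_spans: list[tuple[int, int]]
    peptides: list[PlantedPeptide]
    copy_counts: dict[str, int]


@dataclass
class GroundTruth:
    precursors: dict[str, PrecursorTruth] = field(default_factory=dict)
    peaks: list[PeakTruth] = field(default_factory=list)


def _signal(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(HYDROPHOBIC), size=length - 4))
    return ("M" + body + rng.choice(list(SMALL))
            + rng.choice(list(HYDROPHOBIC)) + rng.choice(list(SMALL)))


def _spacer(rng: np.random.Generator, length: int) -> str:
    # guarantee >= 30% acidic residues, no K/R
    n_acidic = max(3, int(np.ceil(0.34 * length)))
    n_acidic = min(n_acidic, length)
    acidic = rng.choice(list("DE"), size=n_acidic)
    other = rng.choice(list("AGSTPNQH"), size=length - n_acidic)
    residues = np.concatenate([acidic, other])
    rng.shuffle(residues)
    return "".join(residues)


def _peptide(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, bool]:
    lo, hi = cfg.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    pool = "ACDEFGHIKLMNPQRSTVWY" if cfg.allow_internal_basic else NON_BASIC
    body = "".join(rng.choice(list(pool), size=length))
    amidated = bool(rng.random() < cfg.p_terminal_gly)
    if amidated:
        body += "G"
    elif body.endswith("G"):
        # keep unamidated plants unambiguous: no accidental amidation signal
        body = body[:-1] + "A"
    return body, amidated


def generate_precursor_set(config: SimConfig | None = None
                           ) -> tuple[list[PrecursorRecord], GroundTruth]:
    """Simulate precursors with recorded signal, sites and planted peptides."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    records: list[PrecursorRecord] = []
    truth = GroundTruth()
    for p in range(cfg.n_precursors):
        pid = f"SYN{p + 1:03d}"
        sig_len = int(rng.integers(cfg.signal_length_range[0],
                                   cfg.signal_length_range[1] + 1))
        parts: list[str] = [_signal(rng, sig_len)]
        pos = sig_len
        site_spans: list[tuple[int, int]] = []
        planted: list[PlantedPeptide] = []

        def add(block: str) -> int:
            nonlocal pos
            parts.append(block)
            start = pos + 1
            pos += len(block)
            return start

        def add_site() -> None:
            start = add("KR")
            site_spans.append((start, start + 1))

        # leading acidic spacer absorbs any signal-boundary uncertainty
        add(_spacer(rng, int(rng.integers(*_plus1(cfg.spacer_length_range)))))
        add_site()
        n_cassettes = int(rng.integers(*_plus1(cfg.cassettes_per_precursor)))
        for _ in range(n_cassettes):
            pep, amidated = _peptide(rng, cfg)
            n_copies = int(rng.integers(*_plus1(cfg.copy_number_range)))
            for _ in range(n_copies):
                start = add(pep)
                planted.append(PlantedPeptide(
                    precursor_id=pid, start=start, end=pos,
                    sequence=pep, amidated=amidated))
                add_site()
            if rng.random() < cfg.p_acidic_spacer:
                add(_spacer(rng, int(rng.integers(*_plus1(cfg.spacer_length_range)))))
                add_site()
        # C-terminal tail (acidic, spacer-like) so the last site is internal
        add(_spacer(rng, int(rng.integers(*_plus1(cfg.spacer_length_range)))))

        sequence = "".join(parts)
        records.append(PrecursorRecord(id=pid, sequence=sequence,
                                       source_tag="synthetic"))
        copy_counts: dict[str, int] = {}
        for pep in planted:
            copy_counts[pep.sequence] = copy_counts.get(pep.sequence, 0) + 1
        truth.precursors[pid] = PrecursorTruth(
            signal_end=sig_len, site_spans=site_spans,
            peptides=planted, copy_counts=copy_counts)
    return records, truth


def _plus1(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def generate_peak_list(truth: GroundTruth, config: SimConfig | None = None,
                       min_len: int = 8, max_len: int = 22
                       ) -> tuple[list[PeakObservation], GroundTruth]:
    """Emit one noisy peak per detectable planted peptide plus decoy peaks.

    Only peptides whose mature core falls inside the [min_len, max_len]
    window produce a peak.  Decoy peaks are uniform over the observed m/z
    range (or a generic 350-1800 Th survey window when no true peaks exist)
    and are labelled ``noise`` in the returned truth.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + 1)  # decouple from sequence draws
    peaks: list[PeakObservation] = []
    for pid in sorted(truth.precursors):
        for k, pep in enumerate(truth.precursors[pid].peptides):
            core = pep.core_sequence
            if not min_len <= len(core) <= max_len:
                continue
            charge = int(rng.integers(1, 4))
            theo = mass_to_charge(peptide_mass(core, pep.mods), charge)
            mz = theo * (1.0 + rng.normal(0.0, cfg.noise_sd_ppm) * 1e-6)
            label = f"{pid}:{pep.start}-{pep.end}"
            peaks.append(PeakObservation(mz=mz, charge=charge, label=label))
            truth.peaks.append(PeakTruth(mz=mz, charge=charge, source=label))
    if peaks:
        lo = min(p.mz for p in peaks)
        hi = max(p.mz for p in peaks)
        if lo == hi:
            lo, hi = lo * 0.8, hi * 1.2
    else:
        lo, hi = 350.0, 1800.0
    for k in range(cfg.n_decoy_peaks):
        mz = float(rng.uniform(lo, hi))
        charge = int(rng.integers(1, 4))
        peaks.append(PeakObservation(mz=mz, charge=charge, label=f"noise{k + 1}"))
        truth.peaks.append(PeakTruth(mz=mz, charge=charge, source="noise"))
    return peaks, truth
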