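"""Reading and writing the flat-file formats the pipeline touches.

Precursor proteins travel as plain FASTA, observed peaks as a minimal
tab-separated list (``mz<TAB>charge[<TAB>label]``) and all reports as
tab-separated tables with a header row.  Full spectrum formats (mzML, MGF)
are deliberately out of scope: precursor-level matching only needs an
(m/z, charge) pair per observation.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 proteinogenic one-letter codes accepted everywhere in the pipeline.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """Raised for malformed FASTA / peak-list / table input."""


@dataclass(frozen=True)
class PrecursorRecord:
    """One candidate prepropeptide: an identifier plus amino-acid sequence.

    ``description`` keeps any FASTA header text after the first whitespace;
    it is carried as metadata and ignored by the analysis itself.
    """

    id: str
    sequence: str
    source_tag: str = "user"
    description: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record_id=self.id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeakObservation:
    """A single observed (m/z, charge) pair from a peak list."""

    mz: float
    charge: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise FormatError(f"peak m/z must be positive, got {self.mz}")
        if not 1 <= int(self.charge) <= 10:
            raise FormatError(f"peak charge must be in 1..10, got {self.charge}")


def validate_sequence(sequence: str, record_id: str = "?") -> None:
    """Reject empty sequences and any residue outside the 20-letter alphabet.

    Ambiguity codes (B/J/Z/X) and non-standard letters (O/U) are errors: the
    downstream mass arithmetic has no defined value for them.
    """
    if not sequence:
        raise FormatError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in AMINO_ACIDS:
            raise FormatError(
                f"record {record_id!r}: illegal residue {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, source_tag: str = "user") -> list[PrecursorRecord]:
    """Read precursor proteins from a FASTA file.

    Sequences are uppercased; whitespace and a terminal ``*`` stop are
    stripped.  Duplicate identifiers and illegal residues are errors.
    """
    path = Path(path)
    records: list[PrecursorRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            PrecursorRecord(id=rec.id, sequence=seq, source_tag=source_tag,
                            description=desc)
        )
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise FormatError(f"{path}: no records")
    dupes = sorted(k for k, n in seen.items() if n > 1)
    if dupes:
        raise FormatError(f"{path}: duplicate record ids: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[PrecursorRecord], path: str | Path) -> None:
    """Write precursor records as single-line-sequence FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(seqrecords)


def read_peak_list(path: str | Path) -> list[PeakObservation]:
    """Read a tab-separated peak list with header ``mz<TAB>charge[<TAB>label]``."""
    path = Path(path)
    peaks: list[PeakObservation] = []
    with open(path) as handle:
        header = handle.readline()
        cols = header.rstrip("\n").split("\t")
        if not cols or cols[0] != "mz" or len(cols) < 2 or cols[1] != "charge":
            raise FormatError(f"{path}: expected header 'mz\\tcharge[\\tlabel]'")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                mz = float(fields[0])
                charge = int(fields[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric mz/charge") from exc
            if charge < 1:
                raise FormatError(f"{path}:{lineno}: charge must be >= 1")
            label = fields[2] if len(fields) > 2 else ""
            try:
                peaks.append(PeakObservation(mz=mz, charge=charge, label=label))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peak_list(peaks: Iterable[PeakObservation], path: str | Path) -> None:
    rows = [{"mz": p.mz, "charge": p.charge, "label": p.label} for p in peaks]
    write_table(rows, path, columns=["mz", "charge", "label"])


def write_table(
    rows: Sequence[Mapping] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write flat records as a tab-separated table with a header row.

    Floats are rendered with enough digits (9 decimal places) that a
    write -> read round trip preserves every m/z and mass to well below
    1e-6, the precision the matching stage cares about.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
        if columns is not None:
            df = df.reindex(columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format="%.9f")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a report table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
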