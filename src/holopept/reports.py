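"""Human-readable report tables.

Two layouts: a detected-peptide table (one row per peak<->candidate match)
and a per-precursor summary (length, peptide and copy counts, cysteine
content, candidate flag).  Both are plain tab-separated files so they can be
re-read with :func:`holopept.io.read_table`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .annotate import PrecursorAnnotation
from .masses import peptide_mass
from .match import MatchResult
from .ptm import disulfide_capacity

ANNOTATION_COLUMNS = ["precursor_id", "start", "end", "sequence", "mods",
                      "class", "mono_mass"]
MATCH_COLUMNS = ["mz", "charge", "candidate", "mods", "theo_mz", "error_ppm",
                 "is_decoy"]
DETECTED_COLUMNS = ["name", "sequence", "modifications", "mz", "charge",
                    "mono_mass", "precursor_length"]
SUMMARY_COLUMNS = ["precursor_id", "length", "n_peptides", "copy_counts",
                   "n_cysteines", "disulfide_capacity", "candidate_precursor"]


def _mods_string(mods) -> str:
    return ";".join(f"{m.name}@{m.site}" for m in mods) or "none"


def annotation_table(annotations: Iterable[PrecursorAnnotation]) -> pd.DataFrame:
    """Flat per-variant annotation report (one row per mature variant)."""
    rows = []
    for ann in annotations:
        by_span = {(s.start, s.end): c.label
                   for s, c in zip(ann.segments, ann.segment_classes)}
        for pep in ann.mature_peptides:
            rows.append({
                "precursor_id": pep.precursor_id,
                "start": pep.start,
                "end": pep.end,
                "sequence": str(pep),
                "mods": _mods_string(pep.mods),
                "class": by_span.get((pep.start, pep.end), "unassigned"),
                "mono_mass": peptide_mass(pep.core_sequence, pep.mods),
            })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def match_table(matches: Sequence[MatchResult]) -> pd.DataFrame:
    rows = [{
        "mz": m.peak.mz,
        "charge": m.peak.charge,
        "candidate": str(m.candidate),
        "mods": _mods_string(m.candidate.mods),
        "theo_mz": m.theo_mz,
        "error_ppm": m.error_ppm,
        "is_decoy": m.is_decoy,
    } for m in matches]
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def build_reports(annotations: Sequence[PrecursorAnnotation],
                  matches: Sequence[MatchResult] = (),
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The detected-peptide table and the per-precursor summary."""
    lengths = {a.precursor.id: len(a.precursor) for a in annotations}
    detected_rows = []
    for i, m in enumerate(matches):
        detected_rows.append({
            "name": f"match{i + 1}",
            "sequence": str(m.candidate),
            "modifications": _mods_string(m.candidate.mods),
            "mz": m.peak.mz,
            "charge": m.peak.charge,
            "mono_mass": peptide_mass(m.candidate.core_sequence,
                                      m.candidate.mods),
            "precursor_length": lengths.get(
                m.candidate.precursor_id,
                lengths.get("DECOY_" + m.candidate.precursor_id, 0)),
        })
    detected = pd.DataFrame(detected_rows, columns=DETECTED_COLUMNS)

    summary_rows = []
    for ann in annotations:
        seq = ann.precursor.sequence
        copy_str = ";".join(f"{k}x{v}" for k, v in sorted(ann.copy_counts.items())
                            if v > 1) or "-"
        summary_rows.append({
            "precursor_id": ann.precursor.id,
            "length": len(seq),
            "n_peptides": sum(1 for c in ann.segment_classes
                              if c.label == "bioactive_candidate"),
            "copy_counts": copy_str,
            "n_cysteines": seq.count("C"),
            "disulfide_capacity": disulfide_capacity(seq),
            "candidate_precursor": ann.candidate_precursor,
        })
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return detected, summary
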