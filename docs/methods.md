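# Methods

## Scope and model

`holopept` formalizes the standard manual procedure for annotating
neuropeptide precursors (prepropeptides) from protein sequence, as applied
to the circumoral nerve ring (CNR) peptidome of the sea cucumber
*Apostichopus japonicus*. A precursor is modelled as

    signal peptide · [ cleavage site | peptide cassette | acidic spacer ]* 

read N- to C-terminal. Prohormone convertases cleave C-terminal to runs of
1–3 basic residues (Lys/Arg); carboxypeptidase E then removes the exposed
basic residues, so site residues belong to no mature peptide. A mature
peptide ending in Gly adjacent to a processing boundary may be converted by
peptidylglycine α-amidating monooxygenase to the des-Gly peptide amide; an
N-terminal Gln may cyclize to pyroglutamate. Met oxidation and Asn
deamidation are handled as the usual variable search modifications.

## Signal-region handling

Two modes:

* **provided** — the boundary comes from an external predictor or from a
  published annotation; the engine just validates it (10 ≤ end < length,
  end ≤ 45).
* **heuristic** — a transparent stand-in for neural-network predictors:
  for each candidate cut c in [15, 35] the score is the mean Kyte–Doolittle
  hydropathy of residues 5..c−6 (the h-region) plus 1.0 for a small residue
  (A/G/S/C/T/V) at each of positions c−2 and c — the (−3, −1) small-residue
  rule of signal peptidase relative to a cut after c. Ties break toward the
  smaller c. The heuristic is deliberately simple and auditable; it
  recovers a planted canonical boundary (Met + 16 Leu + ASA) within ±2
  residues in 100/100 random polar-tail draws, but it systematically
  undershoots on hydrophobic cores that contain many Ala (Ala is both
  "hydrophobic" and "small", so an early A..A pair can outscore the true
  boundary). The simulator therefore places an acidic spacer directly after
  the signal so that boundary error never corrupts a planted peptide; real
  annotation work should prefer provided boundaries.

## Cleavage sites

Every maximal K/R run of length ≥ 2 is a site (dibasic, tribasic; runs of
4+ are one merged site, cut after the run — no such case occurs in the
reference material). Single K/R sites follow the Veenstra consensus: never
before Pro, and only with another basic residue at −3, −5 or −7. A
`permissive` mode additionally accepts any single Arg not before Pro
(a superset of strict on every sequence), and `off` disables monobasic
detection entirely. The mode is per-run configuration: kisspeptin-type
precursors, for example, contain internal arginines inside a
mass-spectrometry-confirmed intact peptide, and their published site
annotation marks only the dibasic sites — annotating such material with a
blanket monobasic rule over-fragments it.

## Excision, classification, PTM variants

Segments are the maximal stretches strictly between the signal end, site
spans and the precursor end; empty stretches between adjacent sites are
dropped. By construction signal + sites + segments partition the precursor
(a tested invariant). Segments with ≥ 3 Asp/Glu making up ≥ 25% of the
length are labelled acidic spacers (thresholds chosen so that the published
spacer peptides are flagged while the confirmed bioactive peptides are not;
both are configurable); segments shorter than 3 residues stay unassigned.

Variant enumeration per segment: the unmodified base form always;
if the segment is Gly-terminal at a processing boundary, also the des-Gly
amide and the des-Gly free acid (detected peptides lacking both the Gly and
the amide exist, e.g. the AN peptide ANRYNALR, and the engine deliberately
emits both explanations rather than resolving the ambiguity); pyroglutamate
only on N-terminal Gln; up to one Met oxidation and one Asn deamidation by
default (every published modification string carries at most one of each).
Enumeration is deterministic (fewest modifications first, then site order)
and capped at 16 variants per segment. Disulfide capacity (⌊#Cys/2⌋) is
annotated but not applied as a mass delta by default, matching a search
with no cysteine modification configured; tyrosine sulfation is only ever a
boolean flag (CCK-type peptides are predicted sulfated, but the reference
MS search did not include the modification).

A precursor is a *candidate precursor* iff it has a signal region, at least
one cleavage site, and at least one cleavage-site-bounded non-spacer
segment — the same screen de novo precursor-discovery tools apply.

## Mass arithmetic

Free-acid neutral mass = Σ residue monoisotopic masses + H2O; amide
replaces H2O with NH3 (net −0.984016 Da). Deltas: pyroGlu −17.026549,
ox +15.994915, deamidation +0.984016, disulfide −2.015650 per bridge.
m/z = (M + z·1.00727646)/z using the proton mass, not the hydrogen atom
mass — required to reproduce published Orbitrap values. An independent
oracle recomputes every mass from per-residue elemental composition
(pyteomics), sharing no constants with the summation path; the two agree
to < 1e-5 Da on the full reference set and on 1000 random peptides.

The published detected-peptide table heads its mass column "Predicted avg
mass (Da)" but the printed values are monoisotopic (e.g. ANRYNALR
976.520262 monoisotopic vs ≈ 977.09 average); all comparisons are
therefore against monoisotopic masses. One published row (APHAIRPPSG,
944.519199) matches the free acid of the 9-mer APHAIRPPS rather than the
10-mer (1001.540635) and is excluded from numeric validation as an
unexplained inconsistency in the source data; one row (APLADDTAHQVDE) is
printed only to two decimals and is checked at that precision.

## Peak matching and FDR

Matching is precursor-mass only (the reference evidence is m/z + charge per
peptide; fragment-ion scoring is out of scope). Candidates within the
detectability window of 8–22 residues ("longer than seven and shorter than
twenty-three") are mass-indexed and deduplicated by (core, modification
set); each peak is compared at its own charge within a ppm tolerance
(default 10 ppm, appropriate for a 70,000-resolution Orbitrap; the
reference search tolerance is not published, so this is an explicit,
overridable default). `match_peaks` returns *all* candidates in tolerance;
`best_matches` reduces to one assignment per peak for FDR estimation.
Because reversal preserves amino-acid composition, a reversed-decoy
cassette ties its target exactly at the precursor-mass level; as in
standard target-decoy scoring, ties (within 1e-6 ppm, the float summation
round-off) are awarded to the target. FDR = min(1, n_decoy/max(1,
n_target)) over best matches.

## Synthetic data

The simulator emits precursors with the exact architecture above: signal
(Met + hydrophobic core from L/V/I/A/F + small-residue (−3,−1) motif,
length 15–35), a leading acidic spacer, then KR-flanked cassettes (peptide
length 5–25, P(terminal Gly → amide) = 0.6, copy numbers 1–3, 1–3 cassettes
per precursor, spacers interleaved with probability 0.5) and an acidic
tail. Peptide bodies avoid K/R so planted sites are unambiguous (a flag
re-admits them for stress-testing); unamidated plants never end in Gly.
Peaks: one per planted peptide inside the 8–22 window at its theoretical
m/z (charge 1–3) with Gaussian ppm noise (default 2 ppm), plus uniform
noise peaks. All randomness flows through one integer seed; identical seeds
give byte-identical outputs.

What the simulation does *not* emulate: transcriptome assembly error,
chromatographic behaviour, isotope envelopes, missed/non-canonical
cleavages, and sequence composition bias — so passing recovery/FDR
benchmarks demonstrate correctness of the implementation under its own
model, not performance on real tissue extracts. At the default 10 ppm
tolerance, uniform noise rarely lands in the index; the spurious-match
property is exercised with dense noise (2000 peaks/run pooled over ten
seeds), where the pooled decoy-estimated FDR becomes measurably positive.

## Gene structure

Given protein-coding exon lengths, intron phase at junction j is
(cumulative nt) mod 3; phase 1/2 introns interrupt residue ⌊cum/3⌋+1,
phase 0 introns are reported with the two flanking residues (the published
figures underline "residue(s)" without stating the phase-0 convention;
the two-residue reading is adopted). Splice-variant comparison reduces to
shared/exclusive exon-id sets. Spliced genome alignment is out of scope:
exon lengths are inputs.

## Problem sizes and defaults

Validation runs use 20 precursors per simulated set, five sets per
benchmark (~420 planted peptides), 1000 random peptides for the mass
oracle, and 100 draws for the signal-boundary property — sizes at which
every stochastic assertion is stable across seeds while the whole suite
runs in a few seconds.

## Known limitations

* The signal heuristic is not a trained predictor; its accuracy claim is
  limited to the synthetic construct class described above.
* Monobasic-site consensus rules over- or under-call on real precursors;
  mode selection is a per-dataset scientific decision.
* Precursor-mass matching cannot distinguish composition-identical
  sequences (including reversals); only fragment-level evidence could.
* Average-mass mode uses standard average residue masses and is provided
  for completeness; all validation is monoisotopic.
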