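# mirscan

Homology-based discovery of conserved plant microRNAs from EST/GSS
sequence collections, and the analyses that accompany such a survey:
precursor hairpin screening, miRNA target prediction, stem-loop RT-qPCR
primer design, and 2^-ΔΔCt relative expression quantification.

The package is written for researchers mining single-pass sequence
databases (expressed sequence tags and genomic survey sequences) of
species without annotated miRNAs — the setting of the banana
(*Musa* spp.) survey whose published 32-miRNA catalogue and primer sets
ship with the package as reference fixtures — and for anyone who needs a
hermetically testable implementation of this classical pipeline.

## The method

**Discovery.** Known plant mature miRNAs are dereplicated and slid across
every subject read; a window is a candidate homolog when its Hamming
distance to a known miRNA is ≤ 3 (ungapped, both strands, N-windows
excluded). Reads that are low-complexity (DUST-style triplet score > 2.0
per 64-nt window) or protein-coding (an ATG-initiated stop-free ORF ≥ 120
codons over six frames, or external BLASTX evidence) are removed.
Candidate precursor windows are cut around each surviving hit with flanks
from a grid, folded, and screened by the five standard criteria:

1. ≤ 3 nt mismatches against the known miRNA;
2. the mature sequence lies wholly on one arm of a hairpin;
3. < 6 mismatches against the miRNA* on the other arm, with no loop or
   break in the duplex (no symmetric loop > 3 nt, no bulge > 2 nt);
4. precursor A+U content in [30%, 70%];
5. folding MFE ≤ −20 kcal/mol.

Among passing windows the one with minimal energy density (MFE/LP) is
reported. Folding uses an exact base-pair-energy dynamic program by
default (GC −3, AU −2, GU −1 kcal/mol per pair, loop ≥ 3 nt); a ViennaRNA
backend is available.

**Targets.** Sites are scored by the plant expectation penalty
E = Σ penalty(position) over the first 20 miRNA positions — match 0, G:U
0.5, mismatch 1, gap 2, doubled in the seed (positions 2–13) — and
reported at E ≤ 3.0; a disrupted position at 9–11 calls translational
inhibition rather than cleavage. Optional accessibility filtering via the
energy to unpair the site (UPE ≤ 25 kcal/mol, 17/13-nt flanks).

**Quantification.** Stem-loop RT primers (37-nt backbone + reverse
complement of the mature 3' 8 nt), miRNA-specific forward primers (14-nt
tail + mature 5' 10 nt) and a universal reverse primer support qPCR of
mature miRNAs; expression is 2^-ΔΔCt with ΔΔCt = (Ct_miRNA − Ct_5S)_tissue
− (Ct_miRNA − Ct_5S)_calibrator, and miRNA:target anti-correlation is
assessed by Spearman rank correlation across tissues.

Every stage has a synthetic-data generator counterpart
(`mirscan.synthetic`) producing inputs with known ground truth: planted
hairpins, mutated homologs at exact Hamming distance, coding/repeat
decoys, target sites of chosen penalty composition, and Ct tables that
invert exactly at zero noise.

## Worked example

```sh
python examples/catalogue_statistics.py
```

prints, for the packaged banana catalogue:

```
entries: 32
families: 13
mature length histogram: 20 nt: 5, 21 nt: 20, 22 nt: 7
5' nucleotide usage (%): A: 6.2, G: 28.1, U: 65.6
MFE (kcal/mol): min -68.8, max -19.1, mean per entry -45.71, mean per precursor -43.51
A+U (%): min 43.53, max 58.78, mean per entry 49.59, mean per precursor 50.11
origin counts: EST: 16, GSS: 16
arm counts: 3p: 18, 5p: 14
EST discovery frequency: 0.035%
GSS discovery frequency: 0.051%
```

— 32 conserved miRNAs in 13 families, half from ESTs and half from GSSs;
65.6% begin with a 5' uracil (the signature of plant miRNA sorting);
precursor stabilities span −19.1 to −68.8 kcal/mol; and one prediction per
~2,000 GSS reads (0.051%). The other examples
(`discover_mirnas.py`, `predict_targets.py`, `design_primers.py`,
`quantify_expression.py`) each generate a small synthetic input, run one
stage and print what it computes, e.g.

```
$ python examples/design_primers.py
mac-miR156d mature 5'-UUGACAGAAGAUAGAGAGCAC-3'
  stem-loop RT: ctcaactggtgtcgtggagtccggcaattcagttgaggtgctctc
  forward:      acactccagctgggttgacagaag
  universal:    aactggtgtcgtggag
published assays reproduced exactly: 11/12
assays matching the star strand instead: ['miR399a']
```

A thin CLI wraps the same library calls:
`mirscan simulate|predict|stats|targets|primers|quantify|all` (see
`mirscan --help`).

## Layout

- `src/mirscan/` — library modules (`seq_io`, `homology`,
  `candidate_filter`, `folding`, `hairpin`, `stats`, `targets`, `primers`,
  `expression`, `synthetic`, `pipeline`, `cli`)
- `src/mirscan/data/` — the published catalogue and primer fixtures
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, parameter choices, numerical details and
  known limitations
- `tests/` — pytest suite with brute-force oracles and property tests
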