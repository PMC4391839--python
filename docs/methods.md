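# Methods

## Scope and model

`mirscan` implements the classical homology-based ("comparative") route to
conserved plant miRNA discovery from single-pass sequence collections
(ESTs and GSSs), together with the downstream analyses that typically
accompany such a survey: precursor hairpin screening, complementarity-based
target prediction, stem-loop RT-qPCR primer design, and 2^-ΔΔCt relative
quantification. The package also ships a synthetic-data generator that
replaces the genome-scale databases with small inputs whose truth is known
by construction, so every stage is testable offline.

## Homology scan

Known mature miRNAs are dereplicated (one record per distinct sequence
after U/T normalization) and slid across every subject window of equal
length. A window is a homolog when its Hamming distance to the reference
is at most `max_mismatches` (default 3, the conventional conservation
threshold). Matching is deliberately ungapped: the conservation criterion
counts mismatching nucleotides against a fixed-length mature sequence, and
gapped hits would not satisfy it anyway. Both strands are scanned by
default because GSS reads are genomic and EST deposits can be in either
orientation; minus-strand hits are reported in forward-strand coordinates.
Windows containing N are excluded from candidacy. The scan is exact — it
reports every window at or under the threshold, verified against a
brute-force sliding-window oracle — rather than heuristic (no seeding or
E-values, unlike BLAST; any ungapped BLAST hit within the threshold is
found here).

## Repeat / coding filter

Genuine miRNA loci should not sit in low-complexity repeats or
protein-coding sequence. Two desk-scale surrogates stand in for
database-dependent BLAST/BLASTX screening:

* **Low complexity**: a DUST-style triplet-repetition score
  Σ c_t(c_t−1)/2 / (n−1) over 64-nt sliding windows, threshold 2.0 per
  window (the conventional DUST level). Homopolymers and short tandem
  repeats exceed it immediately; uniform random sequence scores ≈ 0.5.
* **Coding potential**: the longest ATG-initiated stop-free reading-frame
  segment over all six frames. The flag threshold is 120 codons: a
  Monte-Carlo null on i.i.d. random reads of single-pass-read length
  (~500 nt) shows ~18% of them carry an ≥80-codon ORF by chance but only
  ~1% carry ≥120, while cDNA-scale coding regions (≥ ~360 nt) are still
  caught. An externally produced BLASTX tabular file can supplement the
  heuristic (any subject with a protein hit at E ≤ 1e-5 is marked coding).

Both verdicts are per-subject, deterministic and idempotent; setting both
thresholds to infinity turns the filter into the identity.

## Folding

Hairpin screening needs a minimum-free-energy secondary structure.
The default backend is an exact Nussinov-style dynamic program over a
simplified, stacking-free energy model: each base pair contributes a fixed
energy (G:C −3, A:U −2, G:U −1 kcal/mol), hairpin loops enclose at least
3 nt, pseudoknots are disallowed. On sequences short enough to enumerate
every nested structure, the DP provably returns the optimum (this
equivalence is a standing test). The model's virtues here are exactness,
determinism and zero external dependencies — which also makes it the
reference for the synthetic generator's truth labels. Its energy scale is
not the thermodynamic nearest-neighbour scale: random RNA folds far more
stably under max-pairing than under real thermodynamics, so the
MFE ≤ −20 kcal/mol criterion is much less discriminating here than with a
thermodynamic engine, and arm/duplex geometry (criteria 2–3) carries the
discrimination. A `ViennaBackend` wrapper over the ViennaRNA bindings
(37 °C parameters) is provided for thermodynamic folding and serves as an
independent cross-check in tests; any object with a
`fold(sequence, blocked=None) -> FoldResult` method can be plugged in.

## Precursor screening

Around each retained hit, candidate windows are cut with left/right flanks
drawn from a grid (default {20, 40, 60, 80, 100, 120, 160} nt each side,
clipped at read ends — published plant pre-miRNA lengths of roughly 77–176
nt motivate those bounds). Each window is folded and screened by five
criteria:

1. ≤ 3 mismatches between the candidate mature and the known miRNA;
2. the mature lies wholly on one hairpin arm (every paired mature position
   pairs strictly downstream, or strictly upstream);
3. fewer than 6 mature positions unpaired in the mature/star duplex, and
   no break — operationalized as no symmetric internal loop > 3 nt and no
   bulge > 2 nt within the duplex (the literature states "no loop or
   break" without quantity; these bounds follow common plant-miRNA
   annotation practice and are configurable);
4. precursor A+U content within [30%, 70%];
5. MFE ≤ −20 kcal/mol.

The miRNA* span is the interval of partner positions of the paired mature
positions, shifted by +2 nt in precursor coordinates — the Dicer 2-nt 3'
overhang convention — and clipped to the precursor. Among windows passing
all five criteria the one with the lowest energy density (MFE/LP) is
selected; density rather than raw MFE, so longer windows cannot win merely
by containing more pairs. Only the single MFE structure is evaluated (no
suboptimal ensemble), matching first-structure usage of classical folding
servers.

## Catalogue statistics

`summarize` reports entry/family counts, the mature-length histogram (from
the catalogued LM values), 5'-terminal nucleotide usage, MFE and A+U
ranges and means, EST/GSS origin counts and arm counts. Star entries count
like any other entry. Means are reported under two conventions — per entry
and per distinct precursor (unique source accession) — because published
summaries do not always state which convention they used; both are printed
in the audit report. Discovery frequency is 100 × predictions / database
size, rounded to 3 decimals.

The packaged banana catalogue is transcribed verbatim from the published
table of 32 predicted miRNAs. One row (mac-miR156) prints a mature length
of 22 nt against a 23-nt printed sequence; the loader flags the
discrepancy (`lm_mismatch`) and warns rather than silently correcting it,
and statistics use the printed LM. One entry (mac-miR5538, MFE −19.1)
violates the stated MFE ≤ −20 criterion; the screening audit reports 31/32
passing rather than reproducing the inconsistency silently.

## Target prediction

Scoring follows the plant-target expectation scheme: over the first
`hspsize` (20) miRNA positions, a Watson-Crick pair costs 0, a G:U wobble
0.5, a mismatch 1.0 and a gap 2.0, doubled within the seed (positions
2–13); sites with E ≤ 3.0 are reported. Because at most one gap is
allowed, the three alignment classes (ungapped, one unopposed miRNA base,
one extra target base) are enumerated exactly and scored vectorized over
all transcript positions — no heuristic alignment. Overlapping sites merge
keeping the minimum-E one. A mismatch or gap at miRNA positions 9–11
predicts translational inhibition, otherwise cleavage. Optional site
accessibility: UPE = MFE(site context folded with the site forced open) −
MFE(free), context = site + 17 nt upstream + 13 nt downstream; sites with
UPE > 25 kcal/mol are discarded when enabled. UPE is off by default (its
energy scale depends on the folding backend, and genome-scale target
counts are out of scope).

## Primer design

Stem-loop RT primer = 37-nt constant backbone + reverse complement of the
mature 3'-terminal 8 nt (45 nt total); forward primer = constant 14-nt
tail + mature 5'-terminal 10 nt (24 nt); one universal reverse primer (a
substring of the backbone). The 8-nt extension was fixed empirically: it
reproduces 11 of the 12 published assay primer sets character-for-character
from their catalogued mature sequences. The twelfth (miR399a) reproduces
exactly when the miR399a* star sequence is used instead — the validation
report flags this rather than deciding which strand the original assay
measured.

## Expression quantification

2^-ΔΔCt with a reference assay (default "5S rRNA") and a calibrator tissue
(default leaf): replicates are averaged on the Ct scale, ΔCt = Ct_assay −
Ct_reference per tissue, ΔΔCt = ΔCt_tissue − ΔCt_calibrator, fold =
2^-ΔΔCt. The computation is invariant to any constant Ct shift. When an
`experiment` column marks independent experiments, the SD of per-experiment
folds is attached. miRNA:target tissue profiles are compared by Spearman
rank correlation (the anti-correlation claim is ordinal); at least 3 shared
tissues are required. No amplification-efficiency correction is applied.

## Synthetic data

Backgrounds are i.i.d. nucleotides at a chosen GC fraction (default 0.5) —
the simplest null that exercises the filters; no codon structure, repeats,
chimeras or vector contamination. Defaults emulate a small EST/GSS excerpt:
500-nt reads, one planted element per read, 30-nt designed flanks, 8-nt
loop. Planted precursors are mature + {A,C}-only loop (unpairable
internally) + reverse-complement star with a chosen number of designed,
isolated duplex mismatches placed ≥2 nt apart and ≥2 nt from the duplex
ends. Truth labels (per-criterion verdicts, MFE) are computed by folding
the designed hairpin with the default backend at generation time, not
assumed. Ct tables are built by inverting the ΔΔCt equations (reference Ct
15, assay calibrator Ct 25) with optional Gaussian noise per measurement.
Every generator is a pure function of its arguments including the seed.

What passing synthetic tests do **not** show: performance on real EST/GSS
data with sequencing error, repeat families, paralogous hairpins and
biased base composition; thermodynamic-scale MFE screening; or genome-scale
target-count reproduction.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open throughout. U/T are interchangeable in
all comparisons. Ties in precursor selection resolve by first-encountered
window on the flank grid; ties in overlapping-site merging by lower start.
Windows clipped at read ends are evaluated as clipped; sequences shorter
than the minimum hairpin (loop 3) fold to the open structure at 0.0.
Empty catalogues, empty hit lists and empty transcriptomes return empty
results rather than raising; empty sequences raise.

## Known limitations

* The default folding model's energies are not thermodynamic; MFE-based
  screening with it is permissive (see Folding above).
* The mature/star duplex profile counts unpaired mature positions in the
  MFE structure; a designed mismatch can be re-paired by the optimizer in
  a shifted register and then surfaces as a bulge/loop break instead of a
  mismatch count — the duplex criterion fails either way, but individual
  counters are structure-dependent.
* With realistic qPCR noise (sd 0.2 cycles, triplicates) the ΔΔCt
  estimator's sampling sd is ≈ 0.23 cycles, so a single fold lands within
  ±15% of truth only ~65% of the time; recovering all planted folds that
  tightly in ≥90% of simulations would require ~4× more replication.
  The noisy-recovery acceptance check records this honestly.
* Target prediction allows at most one gap per site and does not model
  bulged multi-nt target loops.
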