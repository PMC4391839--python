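"""Desk-scale removal of repeat/low-complexity and protein-coding subjects.

Homology hits that land in repetitive or protein-coding reads are almost
never genuine miRNA loci, so subjects are screened before folding:

* low complexity — a DUST-style triplet-repetition score over sliding
  windows; homopolymers and short tandem repeats score high;
* coding potential — the longest ATG-initiated stop-free open reading
  frame over all six frames; long ORFs mark a read as protein-coding.

An externally produced BLASTX tabular file (outfmt 6) can be supplied as
additional evidence: any subject with a protein hit at E <= 1e-5 is
marked coding regardless of the ORF heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .homology import HomologyHit
from .seq_io import SequenceRecord, ValidationError, normalize_dna, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}

# chosen so that i.i.d. random reads of single-pass-read length (~500 nt)
# are flagged at ~1% while cDNA-scale ORFs (>= ~360 nt) are still caught
DEFAULT_CODING_MIN_CODONS = 120
DEFAULT_DUST_WINDOW = 64
DEFAULT_DUST_THRESHOLD = 2.0
DEFAULT_BLASTX_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class FilterConfig:
    coding_min_codons: float = DEFAULT_CODING_MIN_CODONS
    dust_window: int = DEFAULT_DUST_WINDOW
    dust_threshold: float = DEFAULT_DUST_THRESHOLD
    blastx_max_evalue: float = DEFAULT_BLASTX_MAX_EVALUE


@dataclass(frozen=True)
class FilterVerdict:
    """Per-subject audit record of the repeat/coding screen."""

    subject_id: str
    is_low_complexity: bool
    longest_orf_codons: int
    is_coding: bool
    retained: bool

    def __post_init__(self) -> None:
        if self.retained != (not self.is_low_complexity and not self.is_coding):
            raise ValidationError(f"{self.subject_id}: inconsistent filter verdict")


def longest_orf_codons(seq: str) -> int:
    """Longest ATG-initiated stop-free segment, in codons, over 6 frames.

    The count includes the initiating ATG and excludes the stop codon (or
    runs to the end of the frame if no stop follows).  Returns 0 when no
    ATG exists in any frame.
    """
    if not seq:
        raise ValidationError("longest_orf_codons of empty sequence")
    dna = normalize_dna(seq)
    best = 0
    for strand_seq in (dna, reverse_complement(dna, "DNA")):
        for frame in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(frame, len(strand_seq) - 2, 3)
            ]
            run = 0      # codons since the last usable ATG, 0 = not in ORF
            for codon in codons:
                if codon in STOP_CODONS:
                    best = max(best, run)
                    run = 0
                elif run > 0:
                    run += 1
                elif codon == "ATG":
                    run = 1
            best = max(best, run)
    return best


def dust_score(seq: str) -> float:
    """DUST triplet-repetition score of one window.

    score = sum_t c_t (c_t - 1) / 2 / (n_triplets - 1), where c_t counts
    occurrences of each overlapping triplet.  Uniform random sequence
    scores well below 1; homopolymers score ~length/2.
    """
    n = len(seq) - 2
    if n < 2:
        return 0.0
    counts: dict[str, int] = {}
    for i in range(n):
        t = seq[i : i + 3]
        counts[t] = counts.get(t, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (n - 1)


def low_complexity(
    seq: str,
    window: int = DEFAULT_DUST_WINDOW,
    threshold: float = DEFAULT_DUST_THRESHOLD,
) -> bool:
    """True iff any ``window``-length stretch has DUST score > ``threshold``."""
    if not seq:
        raise ValidationError("low_complexity of empty sequence")
    seq = normalize_dna(seq)
    if len(seq) <= window:
        return dust_score(seq) > threshold
    step = max(1, window // 2)
    starts = list(range(0, len(seq) - window + 1, step))
    if starts[-1] != len(seq) - window:
        starts.append(len(seq) - window)
    return any(dust_score(seq[s : s + window]) > threshold for s in starts)


def read_blastx_coding_ids(path: str | Path, max_evalue: float = DEFAULT_BLASTX_MAX_EVALUE) -> set[str]:
    """Subject ids with a BLASTX (outfmt 6) protein hit at E <= max_evalue."""
    coding: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValidationError(f"{path}: line {lineno}: not BLAST outfmt 6")
            if float(fields[10]) <= max_evalue:
                coding.add(fields[0])
    return coding


def classify_subject(
    subject: SequenceRecord,
    config: FilterConfig = FilterConfig(),
    blastx_coding_ids: set[str] | None = None,
) -> FilterVerdict:
    """Repeat/coding verdict for one subject read."""
    lc = low_complexity(subject.residues, config.dust_window, config.dust_threshold)
    orf = longest_orf_codons(subject.residues)
    coding = orf >= config.coding_min_codons
    if blastx_coding_ids and subject.id in blastx_coding_ids:
        coding = True
    return FilterVerdict(
        subject_id=subject.id,
        is_low_complexity=lc,
        longest_orf_codons=orf,
        is_coding=coding,
        retained=not lc and not coding,
    )


def filter_candidates(
    hits: list[HomologyHit],
    subjects: list[SequenceRecord],
    config: FilterConfig = FilterConfig(),
    blastx_coding_ids: set[str] | None = None,
) -> tuple[list[HomologyHit], dict[str, FilterVerdict]]:
    """Drop hits on repetitive or coding subjects.

    Returns the retained hits and one verdict per subject that carries at
    least one hit.  A hit naming an unknown subject raises.
    """
    by_id = {s.id: s for s in subjects}
    verdicts: dict[str, FilterVerdict] = {}
    retained: list[HomologyHit] = []
    for hit in hits:
        if hit.subject_id not in by_id:
            raise ValidationError(f"hit references unknown subject {hit.subject_id!r}")
        if hit.subject_id not in verdicts:
            verdicts[hit.subject_id] = classify_subject(
                by_id[hit.subject_id], config, blastx_coding_ids
            )
        if verdicts[hit.subject_id].retained:
            retained.append(hit)
    return retained, verdicts
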