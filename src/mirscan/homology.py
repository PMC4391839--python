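"""Mismatch-tolerant homology scan of subject sequences against mature miRNAs.

Conserved-miRNA discovery from EST/GSS collections starts by locating, in
each subject read, windows that differ from a known mature miRNA at no
more than ``max_mismatches`` positions (default 3).  Matching is ungapped
Hamming distance over U/T-normalized sequences; both strands are scanned
by default since GSS reads are genomic and ESTs may be deposited in either
orientation.  Windows containing N are excluded unless ``allow_N_match``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_io import SequenceRecord, ValidationError, normalize_rna, reverse_complement

# ambiguity-free base codes; N gets its own code so it never equals a real base
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScanConfig:
    """Homology-scan parameters.

    ``max_mismatches`` is the conservation threshold: a subject window is a
    homolog of a reference mature miRNA if it differs at no more than this
    many positions.
    """

    max_mismatches: int = 3
    strands: str = "BOTH"  # FORWARD or BOTH
    allow_N_match: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")
        if self.strands not in ("FORWARD", "BOTH"):
            raise ValidationError("strands must be FORWARD or BOTH")


@dataclass(frozen=True)
class HomologyHit:
    """An ungapped <=k-mismatch match of a reference miRNA in a subject.

    Coordinates are 0-based half-open on the subject's forward strand,
    also for minus-strand hits.  ``matched_text`` is the subject window as
    read 5'->3' on the matched strand.
    """

    subject_id: str
    reference_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    matched_text: str


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def hamming_mismatches(a: str, b: str, allow_N_match: bool = False) -> int:
    """Number of differing positions between equal-length sequences.

    U and T compare equal.  N mismatches every base (including N) unless
    ``allow_N_match``, in which case N matches anything.
    """
    if len(a) != len(b):
        raise ValidationError(f"length mismatch: {len(a)} vs {len(b)}")
    ea, eb = _encode(a.upper()), _encode(b.upper())
    if allow_N_match:
        return int(np.sum((ea != eb) & (ea != 4) & (eb != 4)))
    return int(np.sum((ea != eb) | ((ea == 4) & (eb == 4))))


def dereplicate_references(refs: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse reference miRNAs to one record per distinct sequence.

    Identity is judged after U/T normalization; the first-seen identifier
    is retained and input order is preserved.
    """
    seen: set[str] = set()
    out: list[SequenceRecord] = []
    for rec in refs:
        key = normalize_rna(rec.residues)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def _scan_strand(ref: np.ndarray, subj: np.ndarray, k: int, allow_n: bool) -> list[tuple[int, int]]:
    """All (offset, mismatches) with mismatches <= k; sliding-window over codes."""
    m, n = len(ref), len(subj)
    if m > n:
        return []
    # windows as a strided 2D view: rows are subject windows
    windows = np.lib.stride_tricks.sliding_window_view(subj, m)
    if allow_n:
        mm = ((windows != ref) & (windows != 4) & (ref != 4)).sum(axis=1)
    else:
        mm = ((windows != ref) | ((windows == 4) & (ref == 4))).sum(axis=1)
        mm[(windows == 4).any(axis=1)] = m + 1  # windows containing N never match
    hits = np.nonzero(mm <= k)[0]
    return [(int(i), int(mm[i])) for i in hits]


def scan_subject(
    ref: SequenceRecord, subject: SequenceRecord, config: ScanConfig = ScanConfig()
) -> list[HomologyHit]:
    """All <=k-mismatch windows of ``subject`` matching ``ref``, each once.

    Minus-strand hits carry forward-strand coordinates; their
    ``matched_text`` is the reverse complement of the forward-strand
    window (the sequence that actually aligned to the reference).
    """
    m, n = len(ref), len(subject)
    hits: list[HomologyHit] = []
    if m > n:
        return hits
    eref = _encode(normalize_rna(ref.residues))
    fwd = _encode(normalize_rna(subject.residues))
    for start, mm in _scan_strand(eref, fwd, config.max_mismatches, config.allow_N_match):
        window = subject.residues[start : start + m]
        hits.append(HomologyHit(subject.id, ref.id, start, start + m, "+", mm, window))
    if config.strands == "BOTH":
        rc = _encode(normalize_rna(reverse_complement(subject.residues, "RNA")))
        for start, mm in _scan_strand(eref, rc, config.max_mismatches, config.allow_N_match):
            # position on reverse strand -> forward-strand coordinates
            f_start = n - (start + m)
            window = subject.residues[f_start : f_start + m]
            hits.append(
                HomologyHit(
                    subject.id,
                    ref.id,
                    f_start,
                    f_start + m,
                    "-",
                    mm,
                    reverse_complement(window, "RNA" if "U" in subject.residues else "DNA"),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def search_database(
    refs: list[SequenceRecord],
    subjects: list[SequenceRecord],
    config: ScanConfig = ScanConfig(),
) -> list[HomologyHit]:
    """Union of :func:`scan_subject` over all reference x subject pairs.

    Result is stably sorted by (subject_id, start, reference_id) and is
    therefore invariant to input ordering.
    """
    hits: list[HomologyHit] = []
    for subject in subjects:
        for ref in refs:
            hits.extend(scan_subject(ref, subject, config))
    hits.sort(key=lambda h: (h.subject_id, h.start, h.reference_id, h.strand))
    return hits


def hits_to_rows(hits: list[HomologyHit]) -> list[dict]:
    """Hits as plain dicts for TSV export."""
    return [
        {
            "subject_id": h.subject_id,
            "reference_id": h.reference_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "mismatches": h.mismatches,
            "matched_text": h.matched_text,
        }
        for h in hits
    ]
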