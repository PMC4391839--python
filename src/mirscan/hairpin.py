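"""Precursor extraction, hairpin geometry and the five screening criteria.

A homology hit alone is weak evidence: a genuine miRNA locus must sit in a
precursor that folds into a stem-loop.  Candidate precursor windows are
cut around each hit (the hit plus flanking sequence on each side), folded,
and screened by five criteria standard in conserved plant miRNA
annotation:

1. the mature candidate differs from the known miRNA at <= 3 nt;
2. the precursor folds into a hairpin with the mature sequence wholly on
   one arm;
3. the mature/star duplex has fewer than 6 mismatched mature positions
   and no large loop or break (operationalized as a symmetric internal
   loop > 3 nt or a bulge > 2 nt);
4. precursor A+U content lies in [30%, 70%];
5. folding MFE <= -20 kcal/mol.

Because the amount of flanking sequence that should be folded is not
knowable a priori, a grid of flank lengths is evaluated and, among the
windows that pass all criteria, the one with the lowest energy density
(MFE / precursor length) is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .folding import FoldResult, fold
from .homology import HomologyHit
from .seq_io import Arm, SequenceRecord, ValidationError, au_content, normalize_rna, reverse_complement

DEFAULT_FLANK_GRID = (20, 40, 60, 80, 100, 120, 160)


class InsufficientDuplexError(ValueError):
    """Too few mature positions are paired to define a miRNA* span."""


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds for the five screening criteria (defaults as stated above)."""

    max_ref_mismatches: int = 3
    duplex_mismatch_limit: int = 6  # exclusive: mismatches must be < limit
    max_symmetric_loop: int = 3
    max_bulge: int = 2
    au_min: float = 30.0
    au_max: float = 70.0
    mfe_max: float = -20.0


@dataclass(frozen=True)
class PrecursorCandidate:
    """A precursor window cut around a homology hit.

    ``sequence`` is the window in RNA form, 5'->3' on the strand carrying
    the mature candidate; ``mature_offset`` locates the mature within it.
    """

    source_hit: HomologyHit
    window_start: int
    window_end: int
    sequence: str
    mature_offset: int
    lm: int

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != len(self.sequence):
            raise ValidationError("window bounds do not match sequence length")
        if not (0 <= self.mature_offset <= self.lp - self.lm):
            raise ValidationError("mature span escapes the precursor window")

    @property
    def lp(self) -> int:
        return len(self.sequence)

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_offset : self.mature_offset + self.lm]


@dataclass(frozen=True)
class HairpinEvaluation:
    """Verdicts of the five criteria for one candidate precursor."""

    arm: Arm
    star_start: int
    star_end: int
    duplex_mismatches: int
    max_symmetric_loop: int
    max_bulge: int
    has_break: bool
    au_percent: float
    mfe: float
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool

    @property
    def passed(self) -> bool:
        return self.c1 and self.c2 and self.c3 and self.c4 and self.c5


def locate_arm(fold_result: FoldResult, mature_offset: int, lm: int) -> Arm:
    """Which hairpin arm holds the mature span.

    FIVE_PRIME if every paired mature position pairs strictly downstream,
    THREE_PRIME if strictly upstream, SPANS_LOOP otherwise (including an
    entirely unpaired mature).
    """
    pt = fold_result.pair_table()
    partners = [(i, pt[i]) for i in range(mature_offset, mature_offset + lm) if pt[i] >= 0]
    if not partners:
        return Arm.SPANS_LOOP
    if all(p > i for i, p in partners):
        return Arm.FIVE_PRIME
    if all(p < i for i, p in partners):
        return Arm.THREE_PRIME
    return Arm.SPANS_LOOP


def derive_star(fold_result: FoldResult, mature_offset: int, lm: int) -> tuple[int, int]:
    """miRNA* span: the region pairing the mature, shifted by the 2-nt 3' overhang.

    The raw star span is the interval of partner positions of the paired
    mature positions; Dicer leaves 2-nt 3' overhangs on both duplex
    strands, which shifts that interval by +2 (in precursor coordinates,
    for either arm).  Returned as a 0-based half-open interval clipped to
    the precursor.  Raises :class:`InsufficientDuplexError` when fewer
    than lm/2 mature positions are paired.
    """
    pt = fold_result.pair_table()
    partners = [pt[i] for i in range(mature_offset, mature_offset + lm) if pt[i] >= 0]
    if len(partners) < lm / 2:
        raise InsufficientDuplexError(
            f"insufficient duplex: only {len(partners)}/{lm} mature positions paired"
        )
    lo, hi = min(partners), max(partners)
    n = len(fold_result.dotbracket)
    star_start = max(0, lo + 2)
    star_end = min(n, hi + 3)
    return star_start, star_end


def duplex_profile(
    fold_result: FoldResult, mature_offset: int, lm: int
) -> tuple[int, int, int]:
    """(duplex_mismatches, max_symmetric_loop, max_bulge) of the mature/star duplex.

    ``duplex_mismatches`` counts mature positions left unpaired in the MFE
    structure.  Between consecutive paired mature positions, an internal
    region with g_m unpaired mature bases opposite g_s unpaired star bases
    contributes a symmetric loop of min(g_m, g_s) and a bulge of
    |g_m - g_s|; maxima over all internal regions are returned.  Unpaired
    runs at the duplex ends count only as mismatches.
    """
    pt = fold_result.pair_table()
    span = range(mature_offset, mature_offset + lm)
    mismatches = sum(1 for i in span if pt[i] < 0)
    paired = [i for i in span if pt[i] >= 0]
    max_sym = 0
    max_bulge = 0
    for a, b in zip(paired, paired[1:]):
        g_m = b - a - 1
        g_s = abs(pt[a] - pt[b]) - 1
        max_sym = max(max_sym, min(g_m, g_s))
        max_bulge = max(max_bulge, abs(g_m - g_s))
    return mismatches, max_sym, max_bulge


def evaluate_criteria(
    candidate: PrecursorCandidate,
    fold_result: FoldResult,
    reference_mismatches: int,
    config: CriteriaConfig = CriteriaConfig(),
) -> HairpinEvaluation:
    """Apply the five screening criteria to a folded candidate precursor."""
    arm = locate_arm(fold_result, candidate.mature_offset, candidate.lm)
    au = au_content(candidate.sequence)
    star_start, star_end = -1, -1
    if arm in (Arm.FIVE_PRIME, Arm.THREE_PRIME):
        try:
            star_start, star_end = derive_star(
                fold_result, candidate.mature_offset, candidate.lm
            )
            mismatches, max_sym, max_bulge = duplex_profile(
                fold_result, candidate.mature_offset, candidate.lm
            )
        except InsufficientDuplexError:
            mismatches, max_sym, max_bulge = candidate.lm, candidate.lm, candidate.lm
    else:
        mismatches, max_sym, max_bulge = candidate.lm, candidate.lm, candidate.lm
    has_break = max_sym > config.max_symmetric_loop or max_bulge > config.max_bulge
    return HairpinEvaluation(
        arm=arm,
        star_start=star_start,
        star_end=star_end,
        duplex_mismatches=mismatches,
        max_symmetric_loop=max_sym,
        max_bulge=max_bulge,
        has_break=has_break,
        au_percent=au,
        mfe=fold_result.mfe,
        c1=reference_mismatches <= config.max_ref_mismatches,
        c2=arm in (Arm.FIVE_PRIME, Arm.THREE_PRIME),
        c3=mismatches < config.duplex_mismatch_limit and not has_break,
        c4=config.au_min <= au <= config.au_max,
        c5=fold_result.mfe <= config.mfe_max,
    )


def extract_window(
    subject: SequenceRecord, hit: HomologyHit, left_flank: int, right_flank: int
) -> PrecursorCandidate:
    """Cut one candidate window around a hit, clipped at subject ends.

    For minus-strand hits the window is reverse-complemented so the mature
    candidate reads 5'->3' within the returned sequence; window
    coordinates stay on the subject's forward strand.
    """
    ws = max(0, hit.start - left_flank)
    we = min(len(subject), hit.end + right_flank)
    window = subject.residues[ws:we]
    lm = hit.end - hit.start
    if hit.strand == "-":
        seq = normalize_rna(reverse_complement(window, "RNA"))
        offset = we - hit.end
    else:
        seq = normalize_rna(window)
        offset = hit.start - ws
    return PrecursorCandidate(hit, ws, we, seq, offset, lm)


def select_precursor(
    subject: SequenceRecord,
    hit: HomologyHit,
    backend=None,
    flank_grid=DEFAULT_FLANK_GRID,
    config: CriteriaConfig = CriteriaConfig(),
) -> tuple[PrecursorCandidate, FoldResult, HairpinEvaluation] | None:
    """Best passing precursor window around a hit, or None.

    Every (left, right) flank combination from ``flank_grid`` is cut,
    folded and screened; windows containing N are skipped.  Among passing
    windows the one with minimum energy density MFE/LP is returned
    (energy-density rather than raw MFE, so longer windows do not win
    merely by containing more pairs).
    """
    best: tuple[PrecursorCandidate, FoldResult, HairpinEvaluation] | None = None
    best_density = 0.0
    seen: set[tuple[int, int]] = set()
    for lf in flank_grid:
        for rf in flank_grid:
            ws = max(0, hit.start - lf)
            we = min(len(subject), hit.end + rf)
            if (ws, we) in seen:
                continue
            seen.add((ws, we))
            if "N" in subject.residues[ws:we]:
                continue
            candidate = extract_window(subject, hit, lf, rf)
            fr = fold(candidate.sequence, backend=backend)
            ev = evaluate_criteria(candidate, fr, hit.mismatches, config)
            if ev.passed:
                density = fr.mfe / candidate.lp
                if best is None or density < best_density:
                    best = (candidate, fr, ev)
                    best_density = density
    return best
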