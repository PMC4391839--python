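"""miRNA target prediction by complementarity penalty ("expectation") scoring.

Plant miRNAs recognise near-perfectly complementary sites on their target
mRNAs.  Each candidate site is scored by a penalty sum E over the scored
region (the first ``hspsize`` nt from the miRNA 5' end): a Watson-Crick
pair costs 0, a G:U wobble 0.5, a mismatch 1.0 and a gap 2.0, with every
penalty doubled inside the seed region (miRNA positions 2-13).  Sites
with E no greater than ``max_expectation`` (default 3.0) are reported.  A
mismatched or gapped position falling in the central region (miRNA
positions 9-11) predicts translational inhibition instead of cleavage.
Optionally, target-site accessibility is estimated as the energy needed
to unpair the site (UPE) within its local context (17 nt upstream, 13 nt
downstream), and inaccessible sites (UPE > 25 kcal/mol) are discarded.

Alignments allow at most one gap, so candidate alignments at a given
site are enumerated exactly: the ungapped one, one with a single
unopposed miRNA base (gap in target), and one with a single extra target
base (gap in miRNA).  Scoring is vectorized over all transcript
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

import numpy as np

from .folding import fold, fold_constrained
from .seq_io import SequenceRecord, ValidationError, normalize_rna

MATCH = "match"
WOBBLE = "wobble"
MISMATCH = "mismatch"
GAP_TARGET = "gap_target"  # miRNA base opposite a gap (deletion in target)
GAP_MIRNA = "gap_mirna"    # target base opposite a gap (insertion in target)

_STATE_PENALTY = {MATCH: 0.0, WOBBLE: 0.5, MISMATCH: 1.0, GAP_TARGET: 2.0, GAP_MIRNA: 2.0}
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# penalty[mirna_code, target_code]
_PENALTY_TABLE = np.ones((5, 5)) * 1.0
for (m, t) in _WC:
    _PENALTY_TABLE[_CODE[m], _CODE[t]] = 0.0
for (m, t) in _WOBBLE_PAIRS:
    _PENALTY_TABLE[_CODE[m], _CODE[t]] = 0.5


@dataclass(frozen=True)
class TargetScanConfig:
    """Scoring thresholds and geometry (all positions 1-based from miRNA 5' end)."""

    max_expectation: float = 3.0
    hspsize: int = 20
    max_upe: float = 25.0
    flank_up: int = 17
    flank_down: int = 13
    central_range: tuple[int, int] = (9, 11)
    seed_range: tuple[int, int] = (2, 13)
    compute_upe: bool = False
    allow_gap: bool = True

    def __post_init__(self) -> None:
        if self.hspsize <= 0 or self.flank_up < 0 or self.flank_down < 0:
            raise ValidationError("lengths must be positive")
        if self.central_range[0] > self.central_range[1]:
            raise ValidationError("bad central_range")


@dataclass(frozen=True)
class TargetSite:
    """One scored miRNA:target duplex on a transcript (0-based half-open)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    expectation: float
    inhibition: str  # CLEAVAGE or TRANSLATION
    alignment: str
    upe: float | None = None


def pair_state(mirna_base: str, target_base: str) -> str:
    """Pairing state of one miRNA base against one target base."""
    pair = (normalize_rna(mirna_base), normalize_rna(target_base))
    if pair in _WC:
        return MATCH
    if pair in _WOBBLE_PAIRS:
        return WOBBLE
    return MISMATCH


def _seed_mult(pos: int, config: TargetScanConfig) -> float:
    lo, hi = config.seed_range
    return 2.0 if lo <= pos <= hi else 1.0


def duplex_penalty(states: list[str], config: TargetScanConfig = TargetScanConfig()) -> float:
    """Expectation E of an alignment given per-column pairing states.

    Columns read from the miRNA 5' end; each consumes one miRNA position
    except ``gap_mirna`` (an extra target base), whose penalty is
    attributed to the next miRNA position.
    """
    e = 0.0
    pos = 0
    for state in states:
        if state not in _STATE_PENALTY:
            raise ValidationError(f"unknown pairing state {state!r}")
        if state == GAP_MIRNA:
            attributed = pos + 1
        else:
            pos += 1
            attributed = pos
        e += _STATE_PENALTY[state] * _seed_mult(attributed, config)
    return e


def _states_for_variant(mir: str, tr: str, end_idx: int, variant: tuple) -> list[str]:
    """Reconstruct alignment columns for one enumerated variant.

    variant is ("ungapped",), ("gap_target", g) with the gap at miRNA
    position g, or ("gap_mirna", g) with an extra target base after
    miRNA position g.
    """
    kind = variant[0]
    states: list[str] = []
    if kind == "ungapped":
        L = variant[1]
        for i in range(L):
            states.append(pair_state(mir[i], tr[end_idx - i]))
    elif kind == "gap_target":
        g, L = variant[1], variant[2]
        for i in range(L):
            pos = i + 1
            if pos < g:
                states.append(pair_state(mir[i], tr[end_idx - i]))
            elif pos == g:
                states.append(GAP_TARGET)
            else:
                states.append(pair_state(mir[i], tr[end_idx - i + 1]))
    elif kind == "gap_mirna":
        g, L = variant[1], variant[2]
        for i in range(g):
            states.append(pair_state(mir[i], tr[end_idx - i]))
        states.append(GAP_MIRNA)
        for i in range(g, L):
            states.append(pair_state(mir[i], tr[end_idx - i - 1]))
    else:  # pragma: no cover
        raise ValueError(kind)
    return states


def _score_all_ends(mir: str, tr: str, config: TargetScanConfig):
    """E for every alignment variant at every possible site end position.

    Returns (E, variants): E has shape (n_variants, len(tr)); E[v, end]
    is the expectation of variant v whose target span ends at ``end``
    (inclusive, the base opposite miRNA position 1).  Impossible
    placements are +inf.
    """
    L = min(len(mir), config.hspsize)
    n = len(tr)
    mcodes = np.array([_CODE[c] for c in mir[:L]])
    tcodes = np.array([_CODE[c] for c in tr])
    mults = np.array([_seed_mult(i + 1, config) for i in range(L)])
    # S[i, end] = penalty of miRNA position i+1 against tr[end - i]
    S = np.full((L, n), np.inf)
    for i in range(L):
        pen = _PENALTY_TABLE[mcodes[i], tcodes] * mults[i]
        if i == 0:
            S[0] = pen
        else:
            S[i, i:] = pen[:-i] if i else pen
    # prefix[g] = sum of S[0..g-1]; suffix[g] = sum of S[g..L-1]
    # (suffix computed directly, not as total - prefix, so +inf sentinels
    # for impossible placements never cancel to NaN)
    prefix = np.vstack([np.zeros(n), np.cumsum(S, axis=0)])
    suffix = np.vstack([np.cumsum(S[::-1], axis=0)[::-1], np.zeros(n)])
    total = prefix[L]
    variants: list[tuple] = [("ungapped", L)]
    rows = [total]
    if config.allow_gap:
        for g in range(1, L + 1):  # unopposed miRNA base at position g
            suf_shifted = np.full(n, np.inf)
            suf_shifted[:-1] = suffix[g][1:]
            if g == L:
                suf_shifted = np.zeros(n)
            e = prefix[g - 1] + _STATE_PENALTY[GAP_TARGET] * _seed_mult(g, config) + suf_shifted
            variants.append(("gap_target", g, L))
            rows.append(e)
        for g in range(1, L):  # extra target base after miRNA position g
            suf_shifted = np.full(n, np.inf)
            suf_shifted[1:] = suffix[g][:-1]
            e = prefix[g] + _STATE_PENALTY[GAP_MIRNA] * _seed_mult(g + 1, config) + suf_shifted
            variants.append(("gap_mirna", g, L))
            rows.append(e)
    return np.vstack(rows), variants


def _alignment_text(mir: str, tr: str, end_idx: int, states: list[str]) -> str:
    """Three-line duplex text: target 5'->3' on top, miRNA 3'->5' below."""
    t_line, marks, m_line = [], [], []
    i, j = 0, 0
    for st in states:
        if st == GAP_TARGET:
            t_line.append("-")
            marks.append(" ")
            m_line.append(mir[i])
            i += 1
        elif st == GAP_MIRNA:
            t_line.append(tr[end_idx - j])
            marks.append(" ")
            m_line.append("-")
            j += 1
        else:
            t_line.append(tr[end_idx - j])
            marks.append({MATCH: "|", WOBBLE: "o"}.get(st, " "))
            m_line.append(mir[i])
            i += 1
            j += 1
    target = "".join(reversed(t_line))
    mk = "".join(reversed(marks))
    mirna = "".join(reversed(m_line))
    return f"target 5' {target} 3'\n          {mk}\nmiRNA  3' {mirna} 5'"


def _central_disrupted(states: list[str], config: TargetScanConfig) -> bool:
    lo, hi = config.central_range
    pos = 0
    for st in states:
        attributed = pos + 1
        if st != GAP_MIRNA:
            pos += 1
            attributed = pos
        if st in (MISMATCH, GAP_TARGET, GAP_MIRNA) and lo <= attributed <= hi:
            return True
    return False


def _target_span(variant: tuple) -> int:
    kind = variant[0]
    if kind == "ungapped":
        return variant[1]
    if kind == "gap_target":
        return variant[2] - 1
    return variant[2] + 1


def find_sites(
    mirna: SequenceRecord,
    transcript: SequenceRecord,
    config: TargetScanConfig = TargetScanConfig(),
    backend=None,
) -> list[TargetSite]:
    """All target sites of one miRNA on one transcript with E <= max_expectation.

    The best-scoring alignment is reported per site end; overlapping
    sites are then merged keeping the minimum-E one.  With
    ``compute_upe`` enabled, sites whose unpairing energy exceeds
    ``max_upe`` are discarded and the UPE is attached to the survivors.
    """
    mir = normalize_rna(mirna.residues)
    tr = normalize_rna(transcript.residues)
    L = min(len(mir), config.hspsize)
    if len(tr) < L - (1 if config.allow_gap else 0):
        return []
    E, variants = _score_all_ends(mir, tr, config)
    # a variant with target span t is only valid when the span fits
    spans = np.array([_target_span(v) for v in variants])
    ends = np.arange(len(tr))
    valid = ends[None, :] - spans[:, None] + 1 >= 0
    E = np.where(valid, E, np.inf)
    best = E.min(axis=0)
    raw: list[TargetSite] = []
    for end_idx in np.nonzero(best <= config.max_expectation)[0]:
        v = int(E[:, end_idx].argmin())
        variant = variants[v]
        states = _states_for_variant(mir, tr, int(end_idx), variant)
        e = duplex_penalty(states, config)
        t_len = _target_span(variant)
        start = int(end_idx) - t_len + 1
        inhibition = "TRANSLATION" if _central_disrupted(states, config) else "CLEAVAGE"
        raw.append(
            TargetSite(
                mirna_id=mirna.id,
                transcript_id=transcript.id,
                start=start,
                end=int(end_idx) + 1,
                expectation=e,
                inhibition=inhibition,
                alignment=_alignment_text(mir, tr, int(end_idx), states),
            )
        )
    merged = _merge_overlapping(raw)
    if config.compute_upe:
        kept = []
        for site in merged:
            upe = upe_estimate(transcript, site, config, backend=backend)
            if upe <= config.max_upe:
                kept.append(
                    TargetSite(
                        site.mirna_id, site.transcript_id, site.start, site.end,
                        site.expectation, site.inhibition, site.alignment, upe,
                    )
                )
        merged = kept
    return merged


def _merge_overlapping(sites: list[TargetSite]) -> list[TargetSite]:
    """Collapse runs of mutually overlapping sites, keeping the min-E site."""
    if not sites:
        return []
    sites = sorted(sites, key=lambda s: (s.start, s.end))
    out: list[TargetSite] = []
    group = [sites[0]]
    group_end = sites[0].end
    for site in sites[1:]:
        if site.start < group_end:
            group.append(site)
            group_end = max(group_end, site.end)
        else:
            out.append(min(group, key=lambda s: (s.expectation, s.start)))
            group = [site]
            group_end = site.end
    out.append(min(group, key=lambda s: (s.expectation, s.start)))
    return out


def upe_estimate(
    transcript: SequenceRecord,
    site: TargetSite,
    config: TargetScanConfig = TargetScanConfig(),
    backend=None,
) -> float:
    """Energy (kcal/mol) to open the target site within its local context.

    The site plus ``flank_up`` nt upstream and ``flank_down`` nt
    downstream is folded twice — freely, and with the site positions
    forced unpaired; UPE is the (non-negative) energy difference.
    """
    tr = normalize_rna(transcript.residues)
    lo = max(0, site.start - config.flank_up)
    hi = min(len(tr), site.end + config.flank_down)
    region = tr[lo:hi]
    blocked = [site.start <= lo + k < site.end for k in range(len(region))]
    free = fold(region, backend=backend)
    constrained = fold_constrained(region, blocked, backend=backend)
    return max(0.0, constrained.mfe - free.mfe)


def predict_targets(
    mirnas: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    config: TargetScanConfig = TargetScanConfig(),
    backend=None,
) -> tuple[list[TargetSite], dict]:
    """Scan every miRNA against every transcript.

    Returns the deterministic, sorted union of sites and a summary with
    per-miRNA pair counts and the mean number of targets per miRNA.
    """
    sites: list[TargetSite] = []
    for mirna in mirnas:
        for transcript in transcripts:
            sites.extend(find_sites(mirna, transcript, config, backend=backend))
    sites.sort(key=lambda s: (s.mirna_id, s.transcript_id, s.start))
    counts = {m.id: 0 for m in mirnas}
    for s in sites:
        counts[s.mirna_id] += 1
    summary = {
        "n_pairs": len(sites),
        "per_mirna": counts,
        "mean_targets_per_mirna": round(mean(counts.values()), 3) if counts else 0.0,
    }
    return sites, summary
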