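"""Synthetic inputs with known ground truth for every pipeline stage.

Real EST/GSS databases are large, genome-specific downloads; this module
replaces them with generated data whose truth is known by construction:

* i.i.d. background reads at a chosen GC fraction;
* precursor hairpins (mature + loop + near-reverse-complement star)
  planted at known coordinates, with a chosen number of designed
  mature/star duplex mismatches;
* homologs of a reference miRNA mutated at an exact Hamming distance;
* protein-coding (long-ORF) and low-complexity decoy reads;
* transcripts carrying target sites of a specified per-position pairing
  composition, hence of known expectation E;
* qPCR Ct tables constructed to invert to chosen fold changes exactly at
  zero noise.

Every generator is a pure function of its arguments including the seed:
identical calls give byte-identical outputs.  Truth labels for planted
hairpins are computed with the package's own base-pair-energy folding
backend, keeping the test suite self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .folding import fold
from .hairpin import CriteriaConfig, PrecursorCandidate, evaluate_criteria
from .homology import HomologyHit
from .seq_io import Origin, SequenceRecord, ValidationError, normalize_rna
from .targets import GAP_MIRNA, GAP_TARGET, MATCH, MISMATCH, WOBBLE, TargetScanConfig, duplex_penalty

_RNA = "ACGU"
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
# bases that neither Watson-Crick nor wobble pair with the key base
_NON_PAIRING = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a discovery-pipeline simulation.

    Defaults emulate a small EST/GSS excerpt: a few hundred-nt single-pass
    reads at balanced GC, each planted element in its own read.
    """

    seed: int = 0
    n_subjects: int = 20
    subject_length: int = 500
    gc_fraction: float = 0.5
    mature_length: int = 21
    loop_length: int = 8
    flank_length: int = 30
    noise_sd_ct: float = 0.2
    replicates: int = 3


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_rna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """i.i.d. RNA at the given GC fraction (G/C and A/U equiprobable within class)."""
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list(_RNA), size=length, p=[p[0], p[1], p[2], p[3]]))


def make_background(
    n_subjects: int,
    subject_length: int,
    gc_fraction: float = 0.5,
    seed: int = 0,
    origin: Origin = Origin.SYNTHETIC,
    prefix: str = "synth",
) -> list[SequenceRecord]:
    """Background subject reads with no planted signal."""
    rng = _rng(seed)
    return [
        SequenceRecord(f"{prefix}_{i:04d}", random_rna(rng, subject_length, gc_fraction), origin)
        for i in range(n_subjects)
    ]


def mutate(seq: str, k: int, seed: int = 0) -> str:
    """Change exactly k positions of ``seq`` to a different base."""
    if k > len(seq):
        raise ValidationError(f"cannot mutate {k} positions of a {len(seq)}-nt sequence")
    rng = _rng(seed)
    seq = normalize_rna(seq)
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in _RNA if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _mutate_star(star: str, mature: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Introduce designed duplex mismatches into a perfect star strand.

    ``star`` is the reverse complement of ``mature``; star position j
    faces mature position lm-1-j.  Mutated bases are chosen to pair with
    the facing mature base neither canonically nor by wobble, and are
    kept >= 2 nt from the star ends so the designed duplex register is
    not shifted.
    """
    lm = len(mature)
    if n_mismatches >= lm - 4:
        raise ValidationError("too many designed duplex mismatches for this mature length")
    eligible = np.arange(2, lm - 2)
    # isolated mismatches: keep paired bases between them so each forms its own loop
    chosen: list[int] = []
    for pos in rng.permutation(eligible):
        if all(abs(pos - c) >= 2 for c in chosen):
            chosen.append(int(pos))
        if len(chosen) == n_mismatches:
            break
    if len(chosen) < n_mismatches:
        raise ValidationError("cannot place designed mismatches far enough apart")
    out = list(star)
    for j in chosen:
        facing = mature[lm - 1 - j]
        options = _NON_PAIRING[facing]
        out[j] = options[int(rng.integers(len(options)))]
    return "".join(out)


def build_precursor(
    mature: str,
    star_mismatches: int = 0,
    loop_length: int = 8,
    seed: int = 0,
) -> str:
    """Designed hairpin: mature + loop + star (mature on the 5' arm).

    The loop is drawn over {A, C} only, so it cannot pair internally; the
    star is the mature's reverse complement with ``star_mismatches``
    designed, isolated mismatches.
    """
    mature = normalize_rna(mature)
    if not (20 <= len(mature) <= 24):
        raise ValidationError("mature length must be 20..24 nt")
    rng = _rng(seed)
    loop = "".join(rng.choice(["A", "C"], size=loop_length))
    star = "".join(_COMPLEMENT[b] for b in reversed(mature))
    if star_mismatches:
        star = _mutate_star(star, mature, star_mismatches, rng)
    return mature + loop + star


def plant_precursor(
    mature: str,
    background: SequenceRecord,
    offset: int,
    star_mismatches: int = 0,
    loop_length: int = 8,
    flank_length: int = 30,
    gc_fraction: float = 0.5,
    seed: int = 0,
    criteria: CriteriaConfig = CriteriaConfig(),
) -> tuple[SequenceRecord, dict]:
    """Insert a designed precursor (with flanks) into a background read.

    Returns the new subject (length = background + insert) and a truth
    record with the planted coordinates and the criteria verdicts of the
    designed hairpin under the package's own folding backend.
    """
    rng = _rng(seed)
    hairpin = build_precursor(mature, star_mismatches, loop_length, seed=seed)
    left = random_rna(rng, flank_length, gc_fraction)
    right = random_rna(rng, flank_length, gc_fraction)
    insert = left + hairpin + right
    if not (0 <= offset <= len(background)):
        raise ValidationError("offset outside the background read")
    residues = background.residues[:offset] + insert + background.residues[offset:]
    subject = SequenceRecord(background.id, residues, background.origin)
    mature_start = offset + flank_length
    # truth labels from the designed hairpin itself
    fr = fold(hairpin)
    candidate = PrecursorCandidate(
        source_hit=HomologyHit(subject.id, "designed", mature_start,
                               mature_start + len(mature), "+", 0, mature),
        window_start=mature_start,
        window_end=mature_start + len(hairpin),
        sequence=normalize_rna(hairpin),
        mature_offset=0,
        lm=len(mature),
    )
    ev = evaluate_criteria(candidate, fr, 0, criteria)
    truth = {
        "subject_id": subject.id,
        "mature": normalize_rna(mature),
        "mature_start": mature_start,
        "mature_end": mature_start + len(mature),
        "hairpin_start": mature_start,
        "hairpin_end": mature_start + len(hairpin),
        "star_mismatches": star_mismatches,
        "criteria": {k: getattr(ev, k) for k in ("c1", "c2", "c3", "c4", "c5")},
        "passed": ev.passed,
        "mfe": fr.mfe,
    }
    return subject, truth


def make_coding_decoy(
    n_codons: int = 120, seed: int = 0, flank: int = 40, gc_fraction: float = 0.5
) -> SequenceRecord:
    """A read containing a clean ORF: ATG + n stop-free codons + stop."""
    rng = _rng(seed)
    sense_codons = []
    stops = {"UAA", "UAG", "UGA"}
    while len(sense_codons) < n_codons:
        codon = random_rna(rng, 3, gc_fraction)
        if codon not in stops:
            sense_codons.append(codon)
    orf = "AUG" + "".join(sense_codons) + "UAA"
    residues = random_rna(rng, flank, gc_fraction) + orf + random_rna(rng, flank, gc_fraction)
    return SequenceRecord(f"coding_decoy_{seed}", residues, Origin.SYNTHETIC)


def make_low_complexity_decoy(length: int = 200, unit: str = "AC", seed: int = 0) -> SequenceRecord:
    """A tandem-repeat read, e.g. (AC)n."""
    residues = (unit * (length // len(unit) + 1))[:length]
    return SequenceRecord(f"repeat_decoy_{seed}", residues, Origin.SYNTHETIC)


def make_transcript_with_site(
    mirna: str,
    states: list[str],
    context_length: int = 300,
    seed: int = 0,
    gc_fraction: float = 0.5,
    config: TargetScanConfig = TargetScanConfig(),
) -> tuple[SequenceRecord, dict]:
    """A transcript carrying one target site of specified pairing states.

    ``states`` lists alignment columns from the miRNA 5' end over the
    scored region (at most ``hspsize`` miRNA positions).  The implied
    target sequence is embedded mid-transcript; the truth records the
    site coordinates and the intended expectation E from
    :func:`mirscan.targets.duplex_penalty`.
    """
    mir = normalize_rna(mirna)
    rng = _rng(seed)
    L = min(len(mir), config.hspsize)
    site_rev: list[str] = []  # target bases 3'->5' (i.e. opposite miRNA 5'->3')
    i = 0
    for st in states:
        if st == GAP_MIRNA:
            facing = mir[i] if i < L else "A"
            site_rev.append(_NON_PAIRING[facing][0])
            continue
        if i >= L:
            raise ValidationError("more non-gap columns than scored miRNA positions")
        m = mir[i]
        if st == MATCH:
            site_rev.append(_COMPLEMENT[m])
        elif st == WOBBLE:
            if m not in _WOBBLE_PARTNER:
                raise ValidationError(f"no wobble partner for miRNA base {m!r} at position {i + 1}")
            site_rev.append(_WOBBLE_PARTNER[m])
        elif st == MISMATCH:
            options = _NON_PAIRING[m]
            site_rev.append(options[int(rng.integers(len(options)))])
        elif st == GAP_TARGET:
            pass  # miRNA base unopposed: no target base
        else:
            raise ValidationError(f"unknown pairing state {st!r}")
        i += 1
    if i != L:
        raise ValidationError(f"states cover {i} of {L} scored miRNA positions")
    site = "".join(reversed(site_rev))  # 5'->3' on the transcript
    left = random_rna(rng, context_length // 2, gc_fraction)
    right = random_rna(rng, context_length - context_length // 2, gc_fraction)
    residues = left + site + right
    transcript = SequenceRecord(f"transcript_{seed}", residues, Origin.TRANSCRIPT)
    truth = {
        "transcript_id": transcript.id,
        "site_start": len(left),
        "site_end": len(left) + len(site),
        "expectation": duplex_penalty(list(states), config),
        "states": list(states),
    }
    return transcript, truth


def make_ct_table(
    planted_folds: dict[str, dict[str, float]],
    tissues: tuple[str, ...] = ("leaf", "root", "flower", "fruit"),
    reference_assay: str = "5S rRNA",
    calibrator_tissue: str = "leaf",
    noise_sd: float = 0.0,
    replicates: int = 3,
    n_experiments: int = 1,
    seed: int = 0,
    reference_ct: float = 15.0,
    assay_base_ct: float = 25.0,
) -> tuple[pd.DataFrame, dict]:
    """Ct table constructed to invert to ``planted_folds`` under 2^-ddCt.

    ``planted_folds`` maps assay -> tissue -> fold relative to the
    calibrator; the calibrator fold is forced to 1.  At ``noise_sd`` 0
    the ddCt computation recovers the folds exactly; otherwise Gaussian
    noise (cycles) is added independently to every measurement.
    """
    rng = _rng(seed)
    rows = []
    for exp in range(1, n_experiments + 1):
        for tissue in tissues:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "assay": reference_assay,
                        "tissue": tissue,
                        "experiment": exp,
                        "replicate": rep,
                        "ct": reference_ct + rng.normal(0.0, noise_sd) if noise_sd else reference_ct,
                    }
                )
    truth_folds: dict[str, dict[str, float]] = {}
    for assay, folds in planted_folds.items():
        folds = dict(folds)
        folds[calibrator_tissue] = 1.0
        truth_folds[assay] = folds
        for exp in range(1, n_experiments + 1):
            for tissue in tissues:
                if tissue not in folds:
                    continue
                if folds[tissue] <= 0:
                    raise ValidationError(f"planted fold for {assay}/{tissue} must be positive")
                clean = assay_base_ct - float(np.log2(folds[tissue]))
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "assay": assay,
                            "tissue": tissue,
                            "experiment": exp,
                            "replicate": rep,
                            "ct": clean + rng.normal(0.0, noise_sd) if noise_sd else clean,
                        }
                    )
    table = pd.DataFrame(rows, columns=["assay", "tissue", "experiment", "replicate", "ct"])
    truth = {
        "planted_folds": truth_folds,
        "reference_assay": reference_assay,
        "calibrator_tissue": calibrator_tissue,
        "noise_sd": noise_sd,
    }
    return table, truth


def simulate_discovery_dataset(
    config: SimulationConfig = SimulationConfig(),
    n_planted: int = 10,
    star_mismatches: int = 0,
    homolog_mismatches: tuple[int, ...] = (),
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """References, subjects and truth for an end-to-end discovery run.

    ``n_planted`` reads receive a criteria-satisfying designed precursor
    of a random mature sequence (one per read); for each value k in
    ``homolog_mismatches`` an additional read receives a precursor whose
    planted mature is mutated at exactly k positions relative to the
    reference.  Remaining reads are pure background.
    """
    rng = _rng(config.seed)
    total_planted = n_planted + len(homolog_mismatches)
    if total_planted > config.n_subjects:
        raise ValidationError("more planted elements than subjects")
    background = make_background(
        config.n_subjects, config.subject_length, config.gc_fraction, seed=config.seed
    )
    references: list[SequenceRecord] = []
    subjects: list[SequenceRecord] = []
    truths: list[dict] = []
    mismatch_plan = [0] * n_planted + list(homolog_mismatches)
    for idx, bg in enumerate(background):
        if idx < total_planted:
            k = mismatch_plan[idx]
            mature = random_rna(_rng(config.seed + 1000 + idx), config.mature_length, 0.5)
            planted_mature = mature if k == 0 else mutate(mature, k, seed=config.seed + 2000 + idx)
            offset = int(rng.integers(0, config.subject_length))
            subject, truth = plant_precursor(
                planted_mature,
                bg,
                offset,
                star_mismatches=star_mismatches,
                loop_length=config.loop_length,
                flank_length=config.flank_length,
                gc_fraction=config.gc_fraction,
                seed=config.seed + 3000 + idx,
            )
            truth["reference_id"] = f"ref_{idx:03d}"
            truth["reference_mismatches"] = k
            references.append(SequenceRecord(f"ref_{idx:03d}", mature, Origin.REFERENCE))
            subjects.append(subject)
            truths.append(truth)
        else:
            subjects.append(bg)
    return references, subjects, truths
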