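"""Sequence and tabular IO plus small alphabet utilities.

The pipeline works on three kinds of nucleotide records: subject EST/GSS
reads being scanned for miRNA homologs, reference mature miRNAs, and mRNA
transcripts used for target prediction.  All of them are held as
:class:`SequenceRecord`.  The module also loads the two packaged fixtures:
the published catalogue of 32 conserved banana miRNAs predicted from
46,111 ESTs and 31,544 GSSs, and the stem-loop qPCR primer sets for the 12
experimentally assayed miRNAs.

Conventions
-----------
* U and T are interchangeable in every comparison; mature miRNAs are kept
  in RNA form (U), primers in DNA form (T).
* Coordinates are 0-based, half-open throughout.
* Residues are upper-cased on input; the alphabet is {A, C, G, T, U, N}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTUN")

_COMPLEMENT_DNA = str.maketrans("ACGTUN", "TGCAAN")
_COMPLEMENT_RNA = str.maketrans("ACGTUN", "UGCAAN")


class Origin(str, Enum):
    """Where a sequence record came from."""

    EST = "EST"
    GSS = "GSS"
    TRANSCRIPT = "TRANSCRIPT"
    REFERENCE = "REFERENCE"
    SYNTHETIC = "SYNTHETIC"


class Arm(str, Enum):
    """Which arm of the precursor hairpin holds the mature miRNA."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"
    SPANS_LOOP = "spans_loop"


class ParseError(ValueError):
    """Malformed input file; message names the offending line or row."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


@dataclass(frozen=True)
class SequenceRecord:
    """One EST/GSS/transcript/reference entry.

    ``residues`` are upper-case over {A, C, G, T, U, N}.
    """

    id: str
    residues: str
    origin: Origin = Origin.SYNTHETIC

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record needs a non-empty id")
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        seq = self.residues.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CatalogueEntry:
    """One predicted-miRNA catalogue row.

    ``lm``/``lp`` are mature and precursor lengths in nt, ``mfe`` the
    precursor minimal folding free energy in kcal/mol and ``au_percent``
    its A+U content.  ``lm_mismatch`` flags rows whose printed mature
    length disagrees with the printed sequence (one such row exists in the
    published catalogue and is transcribed verbatim rather than corrected).
    """

    name: str
    family: str
    mature: str
    accession: str
    origin: Origin
    arm: Arm
    lm: int
    lp: int
    mfe: float
    au_percent: float
    is_star: bool = False
    lm_mismatch: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (20 <= self.lm <= 24):
            raise ValidationError(f"{self.name}: mature length {self.lm} outside 20..24")
        if self.lp < self.lm:
            raise ValidationError(f"{self.name}: precursor shorter than mature")
        if not (0.0 <= self.au_percent <= 100.0):
            raise ValidationError(f"{self.name}: A+U% {self.au_percent} outside [0, 100]")
        if self.mfe > 0:
            raise ValidationError(f"{self.name}: positive MFE {self.mfe}")
        if self.arm not in (Arm.FIVE_PRIME, Arm.THREE_PRIME):
            raise ValidationError(f"{self.name}: arm must be 5p or 3p")


CATALOGUE_COLUMNS = [
    "name", "family", "mature", "accession", "origin", "arm",
    "lm", "lp", "mfe", "au_percent", "is_star",
]


def normalize_rna(seq: str) -> str:
    """Upper-case and convert T to U."""
    return seq.upper().replace("T", "U")


def normalize_dna(seq: str) -> str:
    """Upper-case and convert U to T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str, alphabet: str = "DNA") -> str:
    """Watson-Crick reverse complement.

    U is complemented like T; N maps to N.  ``alphabet`` selects whether
    the result is written with T ("DNA") or U ("RNA").
    """
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(f"illegal characters {sorted(bad)} in sequence")
    if alphabet.upper() == "DNA":
        return seq.translate(_COMPLEMENT_DNA)[::-1]
    if alphabet.upper() == "RNA":
        return seq.translate(_COMPLEMENT_RNA)[::-1]
    raise ValueError(f"unknown alphabet {alphabet!r}")


def au_content(seq: str) -> float:
    """Percent A+U (or A+T) of a sequence: 100 * (A + U/T) / length."""
    if not seq:
        raise ValidationError("au_content of empty sequence")
    seq = seq.upper()
    au = sum(seq.count(b) for b in "AUT")
    return 100.0 * au / len(seq)


def gc_content(seq: str) -> float:
    """Percent G+C of a sequence."""
    if not seq:
        raise ValidationError("gc_content of empty sequence")
    seq = seq.upper()
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def read_fasta(path: str | Path, origin: Origin = Origin.SYNTHETIC) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Case is normalized to upper; U/T are preserved as written.  Records
    are tagged with ``origin``.  Raises :class:`ParseError` on headerless
    leading sequence or illegal residues, naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first and first not in (">", ";"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), origin))
        except ValidationError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqs)


def load_catalogue(path: str | Path | None = None, strict: bool = False) -> list[CatalogueEntry]:
    """Load a miRNA catalogue TSV (defaults to the packaged banana catalogue).

    Columns are fixed (see ``CATALOGUE_COLUMNS``).  Star entries may be
    flagged either through the ``is_star`` column or a ``*`` suffix on the
    name.  Rows whose printed mature length ``lm`` disagrees with the
    length of the printed mature sequence are flagged via ``lm_mismatch``
    and warned about; with ``strict=True`` they raise instead.  Hard
    invariant violations always raise, naming the row.
    """
    if path is None:
        with resources.as_file(
            resources.files("mirscan.data") / "banana_mirna_catalogue.tsv"
        ) as p:
            return load_catalogue(p, strict=strict)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing catalogue columns {sorted(missing)}")
    entries: list[CatalogueEntry] = []
    for idx, row in df.iterrows():
        name = str(row["name"])
        try:
            mature = normalize_rna(str(row["mature"]))
            lm = int(row["lm"])
            mismatch = lm != len(mature)
            entry = CatalogueEntry(
                name=name,
                family=str(row["family"]),
                mature=mature,
                accession=str(row["accession"]),
                origin=Origin(str(row["origin"])),
                arm=Arm(str(row["arm"])),
                lm=lm,
                lp=int(row["lp"]),
                mfe=float(row["mfe"]),
                au_percent=float(row["au_percent"]),
                is_star=bool(int(row["is_star"])) or name.endswith("*"),
                lm_mismatch=mismatch,
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"catalogue row {idx + 1} ({name}): {exc}") from exc
        if entry.lm_mismatch:
            msg = (
                f"catalogue row {idx + 1} ({name}): printed mature length "
                f"{lm} != sequence length {len(mature)}"
            )
            if strict:
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        entries.append(entry)
    names = [e.name for e in entries]
    if len(names) != len(set(names)):
        raise ValidationError(f"{path}: duplicate entry names")
    return entries


def write_catalogue(entries: Sequence[CatalogueEntry], path: str | Path) -> None:
    """Write catalogue entries as TSV with the fixed column set."""
    df = pd.DataFrame(
        [
            {
                "name": e.name,
                "family": e.family,
                "mature": e.mature,
                "accession": e.accession,
                "origin": e.origin.value,
                "arm": e.arm.value,
                "lm": e.lm,
                "lp": e.lp,
                "mfe": e.mfe,
                "au_percent": e.au_percent,
                "is_star": int(e.is_star),
            }
            for e in entries
        ],
        columns=CATALOGUE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Load a qPCR Ct table TSV.

    Required columns: assay, tissue, replicate, ct.  Optional: experiment
    (independent-experiment group for SD propagation).  Ct values must be
    positive.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"assay", "tissue", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing Ct columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise ValidationError(f"{path}: non-positive Ct in row {bad + 1}")
    return df


def load_published_primers() -> pd.DataFrame:
    """The packaged stem-loop RT / forward primer sets for the 12 assayed miRNAs."""
    with resources.as_file(
        resources.files("mirscan.data") / "stemloop_qpcr_primers.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", dtype=str)
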