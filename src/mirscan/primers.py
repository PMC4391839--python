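"""Stem-loop RT-qPCR primer construction for mature miRNAs.

Mature miRNAs (~21 nt) are too short for conventional RT-qPCR, so cDNA is
primed with a hairpin-shaped ("stem-loop") RT primer whose 3' extension
is complementary to the mature miRNA's 3' end.  The PCR then uses a
miRNA-specific forward primer (a universal 5' tail plus the mature 5'
sequence) and a universal reverse primer annealing in the stem-loop
backbone.  The construction rules:

* stem-loop RT primer = 37-nt constant backbone + reverse complement of
  the mature miRNA's 3'-terminal 8 nt (DNA) — 45 nt total;
* forward primer = constant 14-nt tail + the mature miRNA's 5'-terminal
  10 nt as DNA — 24 nt total;
* one universal reverse primer (a substring of the backbone).

Primers are emitted lowercase (comparisons are case-insensitive).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .seq_io import (
    CatalogueEntry,
    ValidationError,
    load_published_primers,
    normalize_dna,
    reverse_complement,
)

STEMLOOP_BACKBONE = "ctcaactggtgtcgtggagtccggcaattcagttgag"
FORWARD_TAIL = "acactccagctggg"
UNIVERSAL_REVERSE = "aactggtgtcgtggag"
RRNA_5S_FORWARD = "tctggtgtcctaggcgta"
RRNA_5S_REVERSE = "attctggcgtcgagctat"

RT_EXTENSION_NT = 8
FORWARD_SPECIFIC_NT = 10


@dataclass(frozen=True)
class PrimerSet:
    """Primer trio for one assayed miRNA (all lowercase DNA)."""

    mirna_id: str
    stemloop_rt: str
    forward: str
    universal_reverse: str = UNIVERSAL_REVERSE


def stemloop_rt_primer(mature: str) -> str:
    """45-nt stem-loop RT primer for a mature miRNA sequence."""
    if len(mature) < RT_EXTENSION_NT:
        raise ValidationError(f"mature sequence shorter than {RT_EXTENSION_NT} nt")
    tail = reverse_complement(normalize_dna(mature)[-RT_EXTENSION_NT:], "DNA")
    return STEMLOOP_BACKBONE + tail.lower()


def forward_primer(mature: str) -> str:
    """24-nt miRNA-specific forward PCR primer."""
    if len(mature) < FORWARD_SPECIFIC_NT:
        raise ValidationError(f"mature sequence shorter than {FORWARD_SPECIFIC_NT} nt")
    return FORWARD_TAIL + normalize_dna(mature)[:FORWARD_SPECIFIC_NT].lower()


def design_primers(mirna_id: str, mature: str) -> PrimerSet:
    """Full primer set for one mature miRNA."""
    return PrimerSet(mirna_id, stemloop_rt_primer(mature), forward_primer(mature))


def _catalogue_lookup(catalogue: list[CatalogueEntry], short_id: str) -> list[CatalogueEntry]:
    """Catalogue entries whose name ends in the assay's short id (e.g. miR156d)."""
    return [e for e in catalogue if e.name.endswith(short_id) and not e.name.endswith(short_id + "*")]


def validate_against_published(
    catalogue: list[CatalogueEntry],
    published: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Check the construction rules against the published primer table.

    For every published assay, primers are regenerated from the
    catalogued mature sequence of the same name and compared
    case-insensitively; if they disagree, the star sequence of the same
    family (name + ``*``) is tried, since an assay may have been designed
    on the star strand.  Returns one row per assay with columns
    ``rt_match``, ``fwd_match``, ``matches_star``.
    """
    if published is None:
        published = load_published_primers()
    rows = []
    for _, prow in published.iterrows():
        short_id = prow["mirna_id"]
        matches = _catalogue_lookup(catalogue, short_id)
        entry = matches[0] if matches else None
        rt_match = fwd_match = star_match = False
        used = None
        if entry is not None:
            used = entry.name
            rt_match = stemloop_rt_primer(entry.mature).lower() == prow["stemloop_rt"].lower()
            fwd_match = forward_primer(entry.mature).lower() == prow["forward"].lower()
            if not (rt_match and fwd_match):
                stars = [e for e in catalogue if e.name == entry.name + "*"]
                if stars:
                    star = stars[0]
                    star_match = (
                        stemloop_rt_primer(star.mature).lower() == prow["stemloop_rt"].lower()
                        and forward_primer(star.mature).lower() == prow["forward"].lower()
                    )
        rows.append(
            {
                "mirna_id": short_id,
                "catalogue_name": used,
                "rt_match": rt_match,
                "fwd_match": fwd_match,
                "exact_match": rt_match and fwd_match,
                "matches_star": star_match,
            }
        )
    return pd.DataFrame(rows)


def primer_table(catalogue: list[CatalogueEntry]) -> pd.DataFrame:
    """Primer sets for every non-star catalogue entry, as a TSV-ready frame."""
    rows = []
    for e in catalogue:
        if e.is_star:
            continue
        ps = design_primers(e.name, e.mature)
        rows.append(
            {
                "mirna_id": ps.mirna_id,
                "stemloop_rt": ps.stemloop_rt,
                "forward": ps.forward,
                "universal_reverse": ps.universal_reverse,
            }
        )
    return pd.DataFrame(rows, columns=["mirna_id", "stemloop_rt", "forward", "universal_reverse"])
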