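"""End-to-end orchestration: homology scan -> filter -> fold -> screen.

`run_predict` drives the whole discovery flow over reference and subject
FASTA collections and returns the predicted catalogue together with the
chosen precursor structures and a per-hit audit trail.  The other
``run_*`` helpers wrap the single-stage entry points with consistent
logging and provenance headers, for use by the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .candidate_filter import FilterConfig, filter_candidates
from .hairpin import (
    DEFAULT_FLANK_GRID,
    CriteriaConfig,
    select_precursor,
)
from .homology import ScanConfig, dereplicate_references, search_database
from .seq_io import CatalogueEntry, Origin, SequenceRecord, write_catalogue
from .stats import summarize, summary_report

logger = logging.getLogger("mirscan")


@dataclass
class PipelineConfig:
    """All tunables of the discovery flow, serializable to one flat JSON."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    flank_grid: tuple[int, ...] = DEFAULT_FLANK_GRID
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class PredictionResult:
    catalogue: list[CatalogueEntry]
    structures: list[dict]  # name, sequence, dotbracket, mfe
    audit: pd.DataFrame
    summary: dict


def _entry_origin(subject: SequenceRecord) -> Origin:
    return subject.origin


def run_predict(
    references: list[SequenceRecord],
    subjects: list[SequenceRecord],
    config: PipelineConfig = PipelineConfig(),
    backend=None,
) -> PredictionResult:
    """Full discovery flow; deterministic for fixed inputs and config.

    Precursors selected from overlapping hits on the same subject window
    are deduplicated, keeping the hit with the fewest reference
    mismatches (ties broken by reference id).
    """
    refs = dereplicate_references(references)
    logger.info("references: %d in, %d after dereplication", len(references), len(refs))
    hits = search_database(refs, subjects, config.scan)
    logger.info("homology scan: %d hits (max %d mismatches)", len(hits), config.scan.max_mismatches)
    retained, verdicts = filter_candidates(hits, subjects, config.filter)
    logger.info("repeat/coding filter: %d of %d hits retained", len(retained), len(hits))
    by_id = {s.id: s for s in subjects}

    selected: dict[tuple, tuple] = {}
    audit_rows: list[dict] = []
    for hit in retained:
        result = select_precursor(
            by_id[hit.subject_id], hit, backend=backend,
            flank_grid=config.flank_grid, config=config.criteria,
        )
        row = {
            "subject_id": hit.subject_id,
            "reference_id": hit.reference_id,
            "start": hit.start,
            "end": hit.end,
            "strand": hit.strand,
            "mismatches": hit.mismatches,
            "precursor_found": result is not None,
        }
        if result is None:
            audit_rows.append(row | {f"c{i}": None for i in range(1, 6)})
            continue
        candidate, fr, ev = result
        row |= {f"c{i}": getattr(ev, f"c{i}") for i in range(1, 6)}
        row |= {"window_start": candidate.window_start, "window_end": candidate.window_end,
                "lp": candidate.lp, "mfe": fr.mfe, "arm": ev.arm.value}
        audit_rows.append(row)
        key = (hit.subject_id, candidate.window_start, candidate.window_end, hit.strand)
        prev = selected.get(key)
        if prev is None or (hit.mismatches, hit.reference_id) < (prev[0].mismatches, prev[0].reference_id):
            selected[key] = (hit, candidate, fr, ev)

    entries: list[CatalogueEntry] = []
    structures: list[dict] = []
    for hit, candidate, fr, ev in selected.values():
        name = f"{hit.reference_id}|{hit.subject_id}:{hit.start}{hit.strand}"
        entries.append(
            CatalogueEntry(
                name=name,
                family=hit.reference_id,
                mature=candidate.mature,
                accession=hit.subject_id,
                origin=_entry_origin(by_id[hit.subject_id]),
                arm=ev.arm,
                lm=candidate.lm,
                lp=candidate.lp,
                mfe=fr.mfe,
                au_percent=round(ev.au_percent, 2),
                is_star=False,
            )
        )
        structures.append(
            {"name": name, "sequence": candidate.sequence,
             "dotbracket": fr.dotbracket, "mfe": fr.mfe}
        )
    order = sorted(range(len(entries)), key=lambda i: entries[i].name)
    entries = [entries[i] for i in order]
    structures = [structures[i] for i in order]
    logger.info("screening: %d precursors pass all criteria", len(entries))
    audit = pd.DataFrame(audit_rows)
    summary = {
        "n_references": len(refs),
        "n_subjects": len(subjects),
        "n_hits": len(hits),
        "n_retained_hits": len(retained),
        "n_filtered_subjects": sum(1 for v in verdicts.values() if not v.retained),
        "n_predicted": len(entries),
    }
    if entries:
        summary["catalogue"] = asdict(summarize(entries))  # type: ignore[arg-type]
    return PredictionResult(entries, structures, audit, summary)


def provenance_header(config: PipelineConfig) -> str:
    return f"# mirscan {__version__} config_hash={config.config_hash()} seed={config.seed}\n"


def write_structures(structures: list[dict], path: str | Path, header: str = "") -> None:
    """Vienna-style text: name line, sequence line, structure line with (mfe)."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for s in structures:
            fh.write(f">{s['name']}\n{s['sequence']}\n{s['dotbracket']} ({s['mfe']:.1f})\n")


def write_prediction(result: PredictionResult, outdir: str | Path, config: PipelineConfig) -> None:
    """Write catalogue TSV, structures, audit TSV and summary JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = provenance_header(config)
    cat_path = outdir / "catalogue.tsv"
    with open(cat_path, "w") as fh:
        fh.write(header)
    tmp = outdir / "_catalogue_body.tsv"
    write_catalogue(result.catalogue, tmp)
    with open(cat_path, "a") as fh:
        fh.write(tmp.read_text())
    tmp.unlink()
    write_structures(result.structures, outdir / "structures.txt", header)
    with open(outdir / "audit.tsv", "w") as fh:
        fh.write(header)
        result.audit.to_csv(fh, sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=str)
        fh.write("\n")
    if result.catalogue:
        (outdir / "summary.txt").write_text(
            header + summary_report(summarize(result.catalogue)) + "\n"
        )
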