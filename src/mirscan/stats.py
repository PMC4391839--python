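"""Summary statistics over a predicted-miRNA catalogue.

Reproduces the descriptive statistics conventionally reported for a
conserved-miRNA discovery study: entry/family counts, mature-length
histogram, 5'-terminal nucleotide usage, MFE and A+U ranges, source
database (EST vs GSS) counts, arm usage, and the per-database discovery
frequency (predictions per database sequence).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seq_io import Arm, CatalogueEntry, Origin, ValidationError


@dataclass(frozen=True)
class CatalogueSummary:
    n_entries: int
    n_families: int
    length_histogram: dict[int, int]
    first_nt_fraction: dict[str, float]  # percent, 1 decimal
    mfe_min: float
    mfe_max: float
    mfe_mean: float
    au_min: float
    au_max: float
    au_mean: float
    origin_counts: dict[str, int]
    arm_counts: dict[str, int]
    # audit extras: per-row vs per-precursor (unique accession) averages, so
    # discrepancies with externally reported averages are visible, not hidden
    mfe_mean_per_precursor: float = field(default=0.0, compare=False)
    au_mean_per_precursor: float = field(default=0.0, compare=False)


def summarize(entries: list[CatalogueEntry]) -> CatalogueSummary:
    """Compute all catalogue summary statistics.

    Star entries count like any other entry.  Percentages are rounded to
    1 decimal, means to 2.  Mature lengths use the catalogued ``lm``.
    """
    if not entries:
        raise ValidationError("cannot summarize an empty catalogue")
    n = len(entries)
    families = {e.family for e in entries}
    lengths = Counter(e.lm for e in entries)
    first = Counter(e.mature[0] for e in entries)
    mfes = [e.mfe for e in entries]
    aus = [e.au_percent for e in entries]
    origins = Counter(e.origin.value for e in entries)
    arms = Counter(e.arm.value for e in entries)
    # one precursor = one source accession
    by_precursor: dict[str, CatalogueEntry] = {}
    for e in entries:
        by_precursor.setdefault(e.accession, e)
    pre_mfes = [e.mfe for e in by_precursor.values()]
    pre_aus = [e.au_percent for e in by_precursor.values()]
    return CatalogueSummary(
        n_entries=n,
        n_families=len(families),
        length_histogram=dict(sorted(lengths.items())),
        first_nt_fraction={b: round(100.0 * c / n, 1) for b, c in sorted(first.items())},
        mfe_min=min(mfes),
        mfe_max=max(mfes),
        mfe_mean=round(sum(mfes) / n, 2),
        au_min=min(aus),
        au_max=max(aus),
        au_mean=round(sum(aus) / n, 2),
        origin_counts={k: origins.get(k, 0) for k in (Origin.EST.value, Origin.GSS.value)},
        arm_counts=dict(sorted(arms.items())),
        mfe_mean_per_precursor=round(sum(pre_mfes) / len(pre_mfes), 2),
        au_mean_per_precursor=round(sum(pre_aus) / len(pre_aus), 2),
    )


def discovery_frequency(n_predicted: int, database_size: int) -> float:
    """Predictions per database sequence, as a percent rounded to 3 decimals."""
    if database_size <= 0:
        raise ValidationError("database_size must be positive")
    return round(100.0 * n_predicted / database_size, 3)


def summary_report(summary: CatalogueSummary) -> str:
    """Human-readable text report of a catalogue summary."""
    lines = [
        f"entries: {summary.n_entries}",
        f"families: {summary.n_families}",
        "mature length histogram: "
        + ", ".join(f"{k} nt: {v}" for k, v in summary.length_histogram.items()),
        "5' nucleotide usage (%): "
        + ", ".join(f"{b}: {p}" for b, p in summary.first_nt_fraction.items()),
        f"MFE (kcal/mol): min {summary.mfe_min}, max {summary.mfe_max}, "
        f"mean per entry {summary.mfe_mean}, mean per precursor {summary.mfe_mean_per_precursor}",
        f"A+U (%): min {summary.au_min}, max {summary.au_max}, "
        f"mean per entry {summary.au_mean}, mean per precursor {summary.au_mean_per_precursor}",
        "origin counts: "
        + ", ".join(f"{k}: {v}" for k, v in summary.origin_counts.items()),
        "arm counts: " + ", ".join(f"{k}: {v}" for k, v in summary.arm_counts.items()),
    ]
    return "\n".join(lines)
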