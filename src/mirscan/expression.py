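"""Relative expression by the 2^-ddCt method and miRNA:target anti-correlation.

qPCR cycle-threshold (Ct) values are normalized to a reference assay
(default "5S rRNA") within each tissue (dCt = Ct_assay - Ct_reference)
and to a calibrator tissue (default leaf): ddCt = dCt_tissue -
dCt_calibrator, fold = 2^-ddCt.  Replicates are averaged on the Ct scale
before any differencing; when an ``experiment`` column marks independent
experiments, the standard deviation of the per-experiment folds is
propagated.

miRNA and target tissue profiles are compared by rank correlation
(Spearman) across tissues: post-transcriptional repression predicts a
negative coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .seq_io import ValidationError

REFERENCE_ASSAY = "5S rRNA"
CALIBRATOR_TISSUE = "leaf"


@dataclass(frozen=True)
class ExpressionRecord:
    """Fold change of one assay in one tissue relative to the calibrator."""

    assay: str
    tissue: str
    mean_ct: float
    delta_ct: float
    delta_delta_ct: float
    fold: float
    sd: float | None = None


def ddct_folds(
    ct: pd.DataFrame,
    reference_assay: str = REFERENCE_ASSAY,
    calibrator_tissue: str = CALIBRATOR_TISSUE,
) -> list[ExpressionRecord]:
    """2^-ddCt fold changes for every (assay, tissue) in a Ct table.

    ``ct`` needs columns assay, tissue, replicate, ct (optionally
    experiment).  The reference assay must be measured in every tissue
    where any assay is measured; missing references raise, naming the
    tissue.  The calibrator tissue's fold is 1 by construction.
    """
    required = {"assay", "tissue", "replicate", "ct"}
    if not required <= set(ct.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    tissues = set(ct["tissue"])
    ref = ct[ct["assay"] == reference_assay]
    for tissue in sorted(tissues):
        if tissue not in set(ref["tissue"]):
            raise ValidationError(f"reference assay {reference_assay!r} missing in tissue {tissue!r}")
    if calibrator_tissue not in tissues:
        raise ValidationError(f"calibrator tissue {calibrator_tissue!r} absent from Ct table")

    mean_ct = ct.groupby(["assay", "tissue"])["ct"].mean()
    ref_ct = mean_ct[reference_assay]

    def fold_of(frame: pd.DataFrame, assay: str, tissue: str) -> tuple[float, float, float, float]:
        m = frame.groupby(["assay", "tissue"])["ct"].mean()
        d = m[(assay, tissue)] - m[(reference_assay, tissue)]
        d0 = m[(assay, calibrator_tissue)] - m[(reference_assay, calibrator_tissue)]
        dd = d - d0
        return m[(assay, tissue)], d, dd, float(2.0 ** (-dd))

    has_experiments = "experiment" in ct.columns and ct["experiment"].nunique() > 1
    records: list[ExpressionRecord] = []
    for assay in sorted(set(ct["assay"]) - {reference_assay}):
        assay_tissues = sorted(set(ct[ct["assay"] == assay]["tissue"]))
        if calibrator_tissue not in assay_tissues:
            raise ValidationError(f"assay {assay!r} not measured in calibrator tissue")
        for tissue in assay_tissues:
            mct = mean_ct[(assay, tissue)]
            d = mct - ref_ct[tissue]
            dd = d - (mean_ct[(assay, calibrator_tissue)] - ref_ct[calibrator_tissue])
            fold = float(2.0 ** (-dd))
            sd = None
            if has_experiments:
                per_exp = []
                for _, grp in ct.groupby("experiment"):
                    try:
                        per_exp.append(fold_of(grp, assay, tissue)[3])
                    except KeyError:
                        continue  # assay/tissue absent from this experiment
                if len(per_exp) > 1:
                    sd = float(np.std(per_exp, ddof=1))
            records.append(ExpressionRecord(assay, tissue, float(mct), float(d), float(dd), fold, sd))
    return records


def records_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    """Expression records as a TSV-ready frame."""
    return pd.DataFrame(
        [
            {
                "assay": r.assay,
                "tissue": r.tissue,
                "mean_ct": r.mean_ct,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "fold": r.fold,
                "sd": r.sd,
            }
            for r in records
        ]
    )


def anticorrelation(
    mirna_folds: dict[str, float], target_folds: dict[str, float]
) -> tuple[float, int]:
    """Spearman rank correlation between miRNA and target tissue profiles.

    Both mappings are tissue -> fold; at least 3 shared tissues are
    required.  Returns (coefficient, sign).
    """
    shared = sorted(set(mirna_folds) & set(target_folds))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared tissues, got {len(shared)}")
    x = [mirna_folds[t] for t in shared]
    y = [target_folds[t] for t in shared]
    rho = float(_scipy_stats.spearmanr(x, y).statistic)
    return rho, int(np.sign(rho))
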