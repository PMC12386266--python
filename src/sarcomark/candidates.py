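"""Aging-DEG -> sarcopenia-candidate filtering.

Aging DEGs (Middle-aged vs Mature, FDR < 0.05) are reduced to candidates by
two filters:

* expression level: average logCPM strictly > 0 (lowly expressed genes have
  limited biomarker value even when their fold change is large);
* quadrant consistency: in the plane of aging logFC (x) against the Pearson
  correlation of the gene's logCPM with total muscle mass per 100 g body
  weight (y), only quadrants I (+/+) and III (-/-) are retained — genes
  whose expression change and muscle-mass association point the same way.

Every rejected gene carries the exact set of filters it failed, so the
selection is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError
from .phenotypes import normalize_per_100g

AXIS = "axis"


@dataclass
class CandidateGene:
    gene_id: str
    aging_logFC: float
    aging_fdr: float
    avg_logCPM: float
    r_muscle: float
    quadrant: int | str
    passes_expression: bool
    passes_consistency: bool

    @property
    def is_candidate(self) -> bool:
        return (
            self.aging_fdr < 0.05 and self.passes_expression and self.passes_consistency
        )


def correlate_with_muscle(
    logcpm: pd.DataFrame, phenotypes: pd.DataFrame
) -> pd.Series:
    """Per-gene Pearson r of logCPM against total muscle mass per 100 g BW.

    Computed across all samples pooled (all five groups).  A zero-variance
    gene or phenotype yields r = 0 (flagged via the series' attrs), never
    NaN.
    """
    ph = phenotypes.set_index("sample_id")
    if set(logcpm.columns) != set(ph.index):
        raise ValidationError("logCPM samples and phenotype samples differ")
    ph = ph.loc[list(logcpm.columns)]
    target = normalize_per_100g(
        ph["total_muscle"].to_numpy(), ph["body_weight"].to_numpy()
    )
    x = logcpm.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = target - target.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    flagged = (sx == 0) | (sy == 0)
    denom = np.where(flagged, 1.0, sx * sy)
    r = np.where(flagged, 0.0, xc @ yc / denom)
    out = pd.Series(r, index=logcpm.index, name="r_muscle")
    out.attrs["zero_variance_genes"] = list(logcpm.index[flagged])
    return out


def assign_quadrant(aging_logfc: float, r_muscle: float) -> int | str:
    """Quadrant of (logFC, r) with logFC on x and r on y; exact zeros -> "axis".

    Quadrants I (+,+) and III (-,-) are the direction-consistent ones kept
    for candidacy; II and IV are discordant; points on either axis are
    excluded because quadrant membership is undefined.
    """
    if not (np.isfinite(aging_logfc) and np.isfinite(r_muscle)):
        raise ValidationError("quadrant assignment requires finite inputs")
    if aging_logfc == 0.0 or r_muscle == 0.0:
        return AXIS
    if aging_logfc > 0:
        return 1 if r_muscle > 0 else 4
    return 2 if r_muscle > 0 else 3


def select_candidates(
    de_aging: pd.DataFrame,
    r_muscle: pd.Series,
    fdr_threshold: float = 0.05,
    logcpm_threshold: float = 0.0,
) -> pd.DataFrame:
    """Apply the FDR, expression and quadrant-consistency filters.

    ``de_aging`` must have columns gene_id, logFC, avg_logCPM, fdr; every
    gene must have an ``r_muscle`` value.  Thresholds are strict as printed
    (fdr < 0.05, logCPM > 0).  Returns the full audit table — one row per
    input gene with its quadrant, a ``candidate`` flag and the
    comma-joined ``failed_filters`` for rejected genes — ordered by gene ID
    so the output is input-order invariant.
    """
    missing = [g for g in de_aging["gene_id"] if g not in r_muscle.index]
    if missing:
        raise ValidationError(
            f"gene(s) missing a muscle correlation: {', '.join(missing[:5])}"
        )
    rows = []
    for rec in de_aging.itertuples(index=False):
        r = float(r_muscle.loc[rec.gene_id])
        quadrant = assign_quadrant(float(rec.logFC), r)
        failed = []
        if not rec.fdr < fdr_threshold:
            failed.append("fdr")
        if not rec.avg_logCPM > logcpm_threshold:
            failed.append("expression")
        if quadrant not in (1, 3):
            failed.append("consistency")
        rows.append(
            {
                "gene_id": rec.gene_id,
                "aging_logFC": float(rec.logFC),
                "aging_fdr": float(rec.fdr),
                "avg_logCPM": float(rec.avg_logCPM),
                "r_muscle": r,
                "quadrant": quadrant,
                "candidate": not failed,
                "failed_filters": ",".join(failed),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "aging_logFC", "aging_fdr", "avg_logCPM", "r_muscle",
                 "quadrant", "candidate", "failed_filters"],
    )
    return out.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
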