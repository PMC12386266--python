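"""Per-gene, per-intervention effect scores and responsiveness filtering.

For an aging DEG with Middle-vs-Mature log2FC ``a`` and intervention-vs-
Middle log2FC ``b``, the default effect score is |b| / |a| — the size of
the intervention-induced change relative to the aging change, so a score
of 1 means the intervention moved expression by as much as aging did.
Whether the intervention actually *reversed* the aging change (opposite
signs) is reported as a flag, not folded into the score, since the score
is built from absolute values.  The reciprocal orientation is available
behind a switch.

Genes are ranked per intervention (1 = most responsive), the top-k lists
are intersected across interventions to find common vs group-specific
responders, and a responsiveness filter keeps genes whose score passes a
threshold (default 1) in every intervention.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ValidationError

logger = logging.getLogger(__name__)

_EPS = 1e-8

ORIENTATIONS = ("reversal_over_aging", "aging_over_reversal")


def effect_score(
    aging_logfc: float,
    intervention_logfc: float,
    orientation: str = "reversal_over_aging",
) -> tuple[float, bool]:
    """Effect score and reversal flag for one (gene, intervention) pair.

    Default orientation: |intervention logFC| / |aging logFC| (higher =
    stronger response); "aging_over_reversal" is the reciprocal.  The
    reversal flag is true when the two fold changes have opposite signs.
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    if abs(aging_logfc) <= _EPS:
        raise ValidationError("undefined score for non-aging gene (|aging logFC| ~ 0)")
    is_reversal = aging_logfc * intervention_logfc < 0
    ratio = abs(intervention_logfc) / abs(aging_logfc)
    if orientation == "aging_over_reversal":
        if abs(intervention_logfc) <= _EPS:
            return float("inf"), is_reversal
        ratio = 1.0 / ratio
    return ratio, is_reversal


def effect_score_table(
    de_aging: pd.DataFrame,
    de_interventions: dict[str, pd.DataFrame],
    gene_ids: list[str] | None = None,
    orientation: str = "reversal_over_aging",
    require_reversal_sign: bool = False,
) -> pd.DataFrame:
    """Long-form score table over a gene universe and several interventions.

    ``de_aging`` / ``de_interventions[label]`` are DE result frames with
    gene_id, logFC, fdr columns.  ``gene_ids`` defaults to all aging genes
    present in every intervention frame.  With ``require_reversal_sign``,
    same-direction (non-reversal) genes get score 0.  Columns: gene_id,
    intervention, aging_logFC, intervention_logFC, effect_score,
    is_reversal, rank (dense 1..n within intervention; ties broken by
    ascending aging FDR then gene ID).
    """
    aging = de_aging.set_index("gene_id")
    rows = []
    for label, de_int in de_interventions.items():
        dint = de_int.set_index("gene_id")
        universe = (
            [g for g in aging.index if g in dint.index] if gene_ids is None
            else list(gene_ids)
        )
        for gid in universe:
            if gid not in aging.index or gid not in dint.index:
                raise ValidationError(f"gene {gid!r} missing from a DE table ({label})")
            a = float(aging.loc[gid, "logFC"])
            b = float(dint.loc[gid, "logFC"])
            score, is_rev = effect_score(a, b, orientation)
            if require_reversal_sign and not is_rev:
                score = 0.0
            rows.append(
                {
                    "gene_id": gid,
                    "intervention": label,
                    "aging_logFC": a,
                    "intervention_logFC": b,
                    "effect_score": score,
                    "is_reversal": is_rev,
                    "aging_fdr": float(aging.loc[gid, "fdr"]),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        table["rank"] = pd.Series(dtype=int)
        return table
    table["rank"] = 0
    for label in de_interventions:
        mask = table["intervention"] == label
        sub = table.loc[mask].sort_values(
            ["effect_score", "aging_fdr", "gene_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        table.loc[sub.index, "rank"] = np.arange(1, mask.sum() + 1)
    return table.reset_index(drop=True)


def rank_by_effect(scores: pd.DataFrame, intervention: str) -> list[str]:
    """Gene IDs of one intervention ordered by descending effect score.

    Ties broken by ascending aging FDR, then lexicographic gene ID —
    deterministic, so reranking the same table reproduces the permutation.
    """
    sub = scores[scores["intervention"] == intervention]
    if sub.empty:
        raise ValidationError(f"no scores for intervention {intervention!r}")
    sub = sub.sort_values(
        ["effect_score", "aging_fdr", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return list(sub["gene_id"])


def top_k(scores: pd.DataFrame, intervention: str, k: int = 20) -> list[str]:
    ordered = rank_by_effect(scores, intervention)
    if k > len(ordered):
        logger.warning(
            "top_k: k=%d exceeds %d scored genes for %s; returning all",
            k, len(ordered), intervention,
        )
    return ordered[:k]


def common_and_specific(
    top_lists: dict[str, list[str]],
) -> tuple[set[str], dict[str, set[str]]]:
    """Intersection across all lists, and per-list exclusive members."""
    if len(top_lists) < 2:
        raise ValidationError("need top lists from >= 2 interventions")
    sets = {label: set(genes) for label, genes in top_lists.items()}
    common = set.intersection(*sets.values())
    specific = {}
    for label, s in sets.items():
        others = set.union(*(o for l, o in sets.items() if l != label))
        specific[label] = s - others
    return common, specific


def select_responsive(
    scores: pd.DataFrame, threshold: float = 1.0, mode: str = "geq"
) -> tuple[set[str], pd.DataFrame]:
    """Genes whose effect score passes the threshold in EVERY intervention.

    ``mode`` chooses the comparison operator: "geq" (>= threshold) or "gt"
    (> threshold).  A gene missing a score in any intervention is excluded
    and recorded in the audit frame with reason "missing_score".  Returns
    (selected genes, audit frame with per-gene pass/fail and reason).
    """
    if mode not in ("geq", "gt"):
        raise ValidationError(f"mode must be 'geq' or 'gt', got {mode!r}")
    if scores.empty:
        return set(), pd.DataFrame(columns=["gene_id", "selected", "reason"])
    interventions = sorted(scores["intervention"].unique())
    op = (lambda s: s >= threshold) if mode == "geq" else (lambda s: s > threshold)
    audit = []
    selected = set()
    for gid, sub in scores.groupby("gene_id"):
        have = set(sub["intervention"])
        if have != set(interventions):
            audit.append({"gene_id": gid, "selected": False, "reason": "missing_score"})
            continue
        if all(op(s) for s in sub["effect_score"]):
            selected.add(gid)
            audit.append({"gene_id": gid, "selected": True, "reason": ""})
        else:
            audit.append({"gene_id": gid, "selected": False, "reason": "below_threshold"})
    return selected, pd.DataFrame(audit)
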