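"""Cross-referencing candidates against a transcription-factor target set.

The final prioritization step intersects three gene sets — the
direction-consistent aging candidates, the intervention-responsive genes,
and a user-supplied TF target list (e.g. a ChEA Klf4 snapshot in GMT
form) — and reports the successive intersection sizes plus per-gene
provenance so the narrowing is auditable.  Pure set algebra: no network
construction or target retrieval happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class CrossRefReport:
    target_set_name: str
    n_candidates: int
    n_responsive: int
    n_targets: int
    n_candidate_and_responsive: int
    intersection: set[str] = field(default_factory=set)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_summary(self) -> dict:
        return {
            "target_set": self.target_set_name,
            "n_candidates": self.n_candidates,
            "n_responsive": self.n_responsive,
            "n_targets": self.n_targets,
            "n_candidate_and_responsive": self.n_candidate_and_responsive,
            "n_hits": len(self.intersection),
            "hits": sorted(self.intersection),
        }


def crossref(
    candidates: set[str],
    responsive: set[str],
    targets: GeneSet,
    case_insensitive: bool = False,
) -> CrossRefReport:
    """candidates ∩ responsive ∩ targets, with an audit trail.

    Empty inputs are warned about, not rejected.  With
    ``case_insensitive``, membership in the target set ignores letter case
    (user-supplied lists often differ in symbol casing) while the reported
    gene IDs keep the candidates' casing.
    """
    for name, s in (("candidates", candidates), ("responsive", responsive)):
        if not s:
            logger.warning("crossref: %s set is empty", name)
    if not targets.members:
        logger.warning("crossref: target set %r is empty", targets.name)
    cand_resp = set(candidates) & set(responsive)
    hits = targets.intersect(cand_resp, case_insensitive=case_insensitive)
    universe = sorted(set(candidates) | set(responsive))
    prov = pd.DataFrame(
        {
            "gene_id": universe,
            "is_candidate": [g in candidates for g in universe],
            "is_responsive": [g in responsive for g in universe],
            "is_tf_target": [
                targets.contains(g, case_insensitive=case_insensitive) for g in universe
            ],
        }
    )
    prov["hit"] = prov["is_candidate"] & prov["is_responsive"] & prov["is_tf_target"]
    return CrossRefReport(
        target_set_name=targets.name,
        n_candidates=len(candidates),
        n_responsive=len(responsive),
        n_targets=len(targets),
        n_candidate_and_responsive=len(cand_resp),
        intersection=hits,
        provenance=prov,
    )
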