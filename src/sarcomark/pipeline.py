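"""End-to-end orchestration with a machine-readable run manifest.

Stage order: (simulate | ingest) -> TMM + logCPM -> dispersion -> aging DE
(Middle vs Mature) -> per-intervention DE (each vs Middle) -> muscle
correlation + candidate filter -> effect scores + top-k + common/specific
-> responsiveness filter -> phenotype correlations -> optional TF-target
cross-reference.  Every stage writes its TSV/CSV/JSON output and records
its surviving gene counts in the manifest, which is deterministic for a
fixed seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as sio
from .candidates import correlate_with_muscle, select_candidates
from .crossref import crossref
from .diffexpr import de_test, estimate_dispersion, log_cpm, tmm_factors
from .io import CountMatrix, ValidationError
from .phenotypes import gene_phenotype_correlations
from .scoring import common_and_specific, effect_score_table, select_responsive, top_k
from .simulate import INTERVENTIONS, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

AGING_CONTRAST = ("Middle", "Mature")


@dataclass
class RunConfig:
    """Everything one run needs; exactly one of counts-paths or simulation."""

    counts_path: str | None = None
    groups_path: str | None = None
    phenotypes_path: str | None = None
    gene_sets_path: str | None = None
    simulation: SimulationConfig | None = None
    fdr_threshold: float = 0.05
    logcpm_threshold: float = 0.0
    effect_threshold: float = 1.0
    effect_mode: str = "geq"  # "geq" or "gt"
    orientation: str = "reversal_over_aging"
    top_k: int = 20
    seed: int = 0
    out_dir: str = "sarcomark_run"

    def __post_init__(self) -> None:
        has_paths = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValidationError(
                "exactly one of (counts_path [+ groups/phenotypes]) or simulation "
                "must be supplied"
            )
        if has_paths and (self.groups_path is None or self.phenotypes_path is None):
            raise ValidationError("counts_path requires groups_path and phenotypes_path")
        if not 0 < self.fdr_threshold < 1:
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.effect_threshold < 0 or self.top_k < 1:
            raise ValidationError("effect_threshold must be >= 0 and top_k >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    def config_hash(self) -> str:
        # analysis-relevant fields only: where outputs land must not change
        # the recorded identity of the run
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StageError(RuntimeError):
    stage: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - formatting
        return f"pipeline stage {self.stage!r} failed: {self.detail}"


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }

    def _write(df: pd.DataFrame, name: str, **kw) -> None:
        path = out_dir / name
        sio.write_table(df, path, seed=config.seed, config_hash=chash, **kw)
        manifest["outputs"][name] = str(path)

    def _stage(name: str):
        logger.info("stage %s", name)

    # ---- input ----------------------------------------------------------
    _stage("input")
    truth = None
    try:
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            cm, phen, truth = simulate_dataset(sim)
            sio.write_counts(cm, out_dir / "counts.tsv", out_dir / "groups.tsv",
                             seed=config.seed, config_hash=chash)
            sio.write_phenotypes(phen, out_dir / "phenotypes.csv",
                                 seed=config.seed, config_hash=chash)
            truth.to_json(out_dir / "truth.json")
            manifest["outputs"]["counts.tsv"] = str(out_dir / "counts.tsv")
            manifest["outputs"]["phenotypes.csv"] = str(out_dir / "phenotypes.csv")
            manifest["outputs"]["truth.json"] = str(out_dir / "truth.json")
        else:
            cm = sio.read_counts(config.counts_path, config.groups_path)
            phen = sio.read_phenotypes(config.phenotypes_path)
    except ValidationError as e:
        raise StageError("input", str(e)) from e
    manifest["stages"]["input"] = {"n_genes": cm.n_genes, "n_samples": cm.n_samples,
                                   "group_sizes": sio.group_sizes(cm.groups)}

    interventions = [g for g in INTERVENTIONS if g in set(cm.groups)]
    if "Middle" not in set(cm.groups) or "Mature" not in set(cm.groups):
        raise StageError("input", "groups must include 'Mature' and 'Middle'")

    # ---- normalization + dispersion -------------------------------------
    _stage("normalize")
    try:
        factors = tmm_factors(cm)
        lcpm, avg_lcpm = log_cpm(cm, factors)
        common_disp, tagwise_disp = estimate_dispersion(cm, factors)
    except ValidationError as e:
        raise StageError("normalize", str(e)) from e
    manifest["stages"]["normalize"] = {
        "common_dispersion": round(float(common_disp), 6),
        "n_samples_normalized": int(len(factors.factors)),
    }

    # ---- differential expression ----------------------------------------
    _stage("de")
    try:
        de_aging = de_test(cm, factors, tagwise_disp, AGING_CONTRAST)
        de_int = {
            g: de_test(cm, factors, tagwise_disp, (g, "Middle")) for g in interventions
        }
    except ValidationError as e:
        raise StageError("de", str(e)) from e
    n_deg = int((de_aging["fdr"] < config.fdr_threshold).sum())
    _write(de_aging, "de_aging.tsv")
    for g, df in de_int.items():
        _write(df, f"de_{g}_vs_Middle.tsv")
    manifest["stages"]["de"] = {
        "n_tested": int(len(de_aging)),
        "n_filtered_all_zero": len(de_aging.attrs["filtered_genes"]),
        "n_aging_degs": n_deg,
    }

    # ---- candidate filter ------------------------------------------------
    _stage("candidates")
    try:
        r_muscle = correlate_with_muscle(lcpm, phen)
        audit = select_candidates(
            de_aging, r_muscle,
            fdr_threshold=config.fdr_threshold,
            logcpm_threshold=config.logcpm_threshold,
        )
    except ValidationError as e:
        raise StageError("candidates", str(e)) from e
    candidate_genes = set(audit.loc[audit["candidate"], "gene_id"])
    _write(audit, "candidates.tsv")
    manifest["stages"]["candidates"] = {
        "n_input": int(len(audit)),
        "n_candidates": len(candidate_genes),
        "n_failed_fdr": int(audit["failed_filters"].str.contains("fdr").sum()),
        "n_failed_expression": int(audit["failed_filters"].str.contains("expression").sum()),
        "n_failed_consistency": int(audit["failed_filters"].str.contains("consistency").sum()),
    }

    # ---- effect scores ---------------------------------------------------
    _stage("scores")
    try:
        scorable = sorted(
            g for g in candidate_genes
            if all(g in set(df["gene_id"]) for df in de_int.values())
        )
        scores = effect_score_table(
            de_aging, de_int, gene_ids=scorable, orientation=config.orientation
        )
    except ValidationError as e:
        raise StageError("scores", str(e)) from e
    _write(scores, "effect_scores.tsv")
    tops = {g: top_k(scores, g, config.top_k) for g in interventions} if scorable else {}
    if len(tops) >= 2:
        common, specific = common_and_specific(tops)
    else:
        common, specific = set(), {}
    manifest["stages"]["scores"] = {
        "n_scored": len(scorable),
        "top_k": {g: t for g, t in tops.items()},
        "common_top_genes": sorted(common),
        "n_specific": {g: len(s) for g, s in specific.items()},
    }

    # ---- responsiveness filter ------------------------------------------
    _stage("responsive")
    responsive, resp_audit = select_responsive(
        scores, threshold=config.effect_threshold, mode=config.effect_mode
    )
    _write(resp_audit, "responsive.tsv")
    manifest["stages"]["responsive"] = {"n_responsive": len(responsive)}

    # ---- phenotype correlations -----------------------------------------
    _stage("correlate")
    corr_genes = sorted(responsive) if responsive else sorted(candidate_genes)[:20]
    if corr_genes:
        corr = gene_phenotype_correlations(lcpm, phen, gene_ids=corr_genes)
        _write(corr, "phenotype_correlations.tsv")
        manifest["stages"]["correlate"] = {"n_genes": len(corr_genes)}
    else:
        manifest["stages"]["correlate"] = {"n_genes": 0}

    # ---- TF-target cross-reference --------------------------------------
    if config.gene_sets_path is not None:
        _stage("crossref")
        try:
            gene_sets = sio.read_gene_sets(config.gene_sets_path)
        except ValidationError as e:
            raise StageError("crossref", str(e)) from e
        reports = [crossref(candidate_genes, responsive, gs) for gs in gene_sets]
        manifest["stages"]["crossref"] = [r.to_summary() for r in reports]
        if reports:
            _write(pd.concat([r.provenance for r in reports],
                             keys=[r.target_set_name for r in reports],
                             names=["target_set"]).reset_index(level=0),
                   "crossref.tsv")

    # ---- recovery against planted truth (simulation runs only) ----------
    if truth is not None:
        planted = truth.aging_genes
        recovered = candidate_genes & planted
        manifest["stages"]["truth_recovery"] = {
            "n_planted_aging": len(planted),
            "n_candidates_planted": len(recovered),
            "false_candidates": len(candidate_genes - planted),
        }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["outputs"]["manifest.json"] = str(out_dir / "manifest.json")
    return manifest
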