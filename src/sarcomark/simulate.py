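"""Synthetic study generator: group-structured NB counts and mouse phenotypes.

Emulates a five-group murine muscle-aging design — a young Mature control,
an aged Middle control, and three dietary interventions (allulose ALL and
low/high molecular weight collagen hydrolysate LCOL/HCOL) applied to aged
animals — with a planted ground truth for recovery testing:

* a fraction of genes get a nonzero Middle-vs-Mature log2 fold change
  (signs random) — the "aging" genes;
* per intervention, a subset of aging genes are "reversal" genes whose
  intervention-group mean moves back toward the Mature level (planted
  intervention logFC = -reversal_fraction * aging logFC, applied on top of
  the Middle mean); all other aging genes keep the Middle mean under
  intervention;
* per-mouse phenotypes are linear in the standardized logCPM of planted
  driver genes plus Gaussian noise, so gene–phenotype correlations have a
  known closed form; the muscle-to-fat ratio is computed, never sampled.

Counts are NB with Var = mu + phi mu^2 and per-sample library sizes drawn
with a configurable coefficient of variation.  Everything is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError, validate_phenotypes

DEFAULT_GROUP_SIZES = {"Mature": 6, "Middle": 6, "ALL": 4, "LCOL": 4, "HCOL": 4}
INTERVENTIONS = ("ALL", "LCOL", "HCOL")

# per-phenotype (baseline, natural scale) in the units of the field:
# grams for masses, mm for thickness, gram-force for grip strength.  The
# Mature group is lighter; aged groups carry more body mass and fat.
_PHENOTYPE_BASELINES = {
    "quadriceps_w": (0.40, 0.03),
    "tibialis_anterior_w": (0.10, 0.008),
    "gastrocnemius_w": (0.30, 0.02),
    "hindlimb_thickness": (7.0, 0.25),
    "total_muscle": (12.0, 0.8),
    "total_fat": (6.0, 0.6),
    "grip_strength": (180.0, 12.0),
}
_BODY_WEIGHT_BASE = {"Mature": 28.0, "Middle": 38.0, "ALL": 36.0, "LCOL": 36.0, "HCOL": 36.0}
_BODY_WEIGHT_SD = 1.5


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_genes: int = 2000
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    baseline_log_mean_range: tuple[float, float] = (3.0, 10.0)
    # BCV ~ 0.2 (phi = BCV^2), the canonical value for genetically identical
    # model organisms such as inbred mice
    dispersion: float = 0.04
    per_gene_dispersion: bool = False
    lib_size_mean: int = 1_000_000
    lib_size_cv: float = 0.1
    frac_aging_genes: float = 0.1
    aging_lfc_magnitude: float | tuple[float, float] = 1.0
    frac_reversal_per_intervention: float = 0.3
    reversal_overlap: float = 0.5
    reversal_fraction_of_aging_lfc: float = 1.0
    frac_muscle_coupled: float = 0.5
    n_phenotype_drivers: int = 3
    phenotype_coupling: float = 1.0
    phenotype_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValidationError("n_genes must be >= 10 (degenerate dispersion estimation)")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {g!r} size must be >= 2")
        for name in ("frac_aging_genes", "frac_reversal_per_intervention",
                     "frac_muscle_coupled", "reversal_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.lib_size_cv < 0 or self.phenotype_noise_sd < 0:
            raise ValidationError("lib_size_cv and phenotype_noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_log_mean_range"] = list(self.baseline_log_mean_range)
        if isinstance(self.aging_lfc_magnitude, tuple):
            d["aging_lfc_magnitude"] = list(self.aging_lfc_magnitude)
        return d


@dataclass
class SyntheticTruth:
    """Planted ground truth: which genes carry which effects.

    ``aging_lfc`` maps gene ID -> signed Middle-vs-Mature log2FC;
    ``reversal_lfc`` maps intervention -> {gene ID -> signed
    intervention-vs-Middle log2FC} (always sign-opposed to the aging logFC);
    ``phenotype_drivers`` maps phenotype -> {gene ID -> coupling}.
    """

    aging_lfc: dict[str, float] = field(default_factory=dict)
    reversal_lfc: dict[str, dict[str, float]] = field(default_factory=dict)
    phenotype_drivers: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        aging = set(self.aging_lfc)
        for intervention, revs in self.reversal_lfc.items():
            extra = set(revs) - aging
            if extra:
                raise ValidationError(
                    f"reversal genes not in aging set ({intervention}): {sorted(extra)[:3]}"
                )
            for g, lfc in revs.items():
                if lfc * self.aging_lfc[g] >= 0:
                    raise ValidationError(
                        f"reversal logFC of {g} must oppose its aging logFC"
                    )

    @property
    def aging_genes(self) -> set[str]:
        return set(self.aging_lfc)

    def reversal_genes(self, intervention: str) -> set[str]:
        return set(self.reversal_lfc.get(intervention, {}))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # stable across processes (unlike builtin hash): crc32 of the stream name
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the NB count matrix and its planted truth.

    Gene baseline abundances are log2-uniform over ``baseline_log_mean_range``
    (interpreted as log2 expected counts at the mean library size); group
    means are the baseline shifted by the planted log2FCs; counts are
    NB(mu * L_s / L_mean, phi).  Library sizes are truncated-normal with
    mean ``lib_size_mean`` and CV ``lib_size_cv``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    gene_ids = np.array([f"g{i:05d}" for i in range(G)])
    groups_order = list(config.group_sizes)
    sample_ids, sample_groups = [], []
    for g in groups_order:
        for k in range(config.group_sizes[g]):
            sample_ids.append(f"{g}_{k + 1}")
            sample_groups.append(g)
    n = len(sample_ids)

    lo, hi = config.baseline_log_mean_range
    base = 2.0 ** rng.uniform(lo, hi, size=G)
    # rescale so the expected column total at the mean library size is
    # lib_size_mean; baseline_log_mean_range then sets relative abundances
    base *= config.lib_size_mean / base.sum()

    n_aging = int(round(config.frac_aging_genes * G))
    aging_idx = rng.choice(G, size=n_aging, replace=False)
    mag = config.aging_lfc_magnitude
    if isinstance(mag, tuple):
        mags = rng.uniform(mag[0], mag[1], size=n_aging)
    else:
        mags = np.full(n_aging, float(mag))
    signs = rng.choice([-1.0, 1.0], size=n_aging)
    aging_lfc_arr = mags * signs
    aging_lfc = {gene_ids[i]: float(l) for i, l in zip(aging_idx, aging_lfc_arr)}

    # reversal sets share a common core across interventions (fraction
    # reversal_overlap of each set), emulating a shared nutrition-responsive
    # program plus intervention-specific responders
    n_rev = int(round(config.frac_reversal_per_intervention * n_aging))
    n_core = int(round(config.reversal_overlap * n_rev))
    core = rng.choice(n_aging, size=n_core, replace=False)
    rest = np.setdiff1d(np.arange(n_aging), core)
    reversal_lfc: dict[str, dict[str, float]] = {}
    for intervention in INTERVENTIONS:
        if intervention not in config.group_sizes:
            continue
        extra = rng.choice(rest, size=min(n_rev - n_core, rest.size), replace=False)
        pick = np.concatenate([core, extra]).astype(int)
        reversal_lfc[intervention] = {
            gene_ids[aging_idx[j]]: float(
                -config.reversal_fraction_of_aging_lfc * aging_lfc_arr[j]
            )
            for j in pick
        }

    # phenotype drivers: signed so that a gene's muscle correlation matches
    # the sign of its aging logFC (direction-consistent by construction)
    n_coupled = int(round(config.frac_muscle_coupled * n_aging))
    coupled = rng.choice(n_aging, size=n_coupled, replace=False)
    phenotype_drivers: dict[str, dict[str, float]] = {}
    if n_coupled:
        phenotype_drivers["total_muscle"] = {
            gene_ids[aging_idx[j]]: float(
                config.phenotype_coupling * np.sign(aging_lfc_arr[j])
            )
            for j in coupled
        }
        for ph in _PHENOTYPE_BASELINES:
            if ph in ("total_muscle",):
                continue
            k = min(config.n_phenotype_drivers, n_coupled)
            pick = rng.choice(coupled, size=k, replace=False)
            phenotype_drivers[ph] = {
                gene_ids[aging_idx[j]]: float(
                    config.phenotype_coupling * np.sign(aging_lfc_arr[j])
                )
                for j in pick
            }
    truth = SyntheticTruth(
        aging_lfc=aging_lfc, reversal_lfc=reversal_lfc, phenotype_drivers=phenotype_drivers
    )

    # per-(gene, group) mean shift in log2 space: aged groups (Middle and all
    # interventions) start from the Middle mean; reversals act on top of it
    lfc = np.zeros((G, len(groups_order)))
    for i, l in zip(aging_idx, aging_lfc_arr):
        for c, grp in enumerate(groups_order):
            if grp != "Mature":
                lfc[i, c] = l
    for intervention, revs in reversal_lfc.items():
        c = groups_order.index(intervention)
        for gid, l in revs.items():
            i = int(gid[1:])
            lfc[i, c] += l

    lib = config.lib_size_mean * np.maximum(
        rng.normal(1.0, config.lib_size_cv, size=n), 0.05
    )
    phi = (
        2.0 ** rng.uniform(np.log2(config.dispersion / 4), np.log2(config.dispersion * 4), G)
        if config.per_gene_dispersion
        else np.full(G, config.dispersion)
    )

    counts = np.empty((G, n), dtype=np.int64)
    col_group = np.array([groups_order.index(g) for g in sample_groups])
    for s in range(n):
        mu = base * 2.0 ** lfc[:, col_group[s]] * (lib[s] / config.lib_size_mean)
        # NB via gamma-Poisson: shape 1/phi, scale mu*phi
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts[:, s] = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups=pd.Series(sample_groups, index=sample_ids),
    )
    return cm, truth


def simulate_phenotypes(
    counts: CountMatrix, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-mouse phenotype table coupled to the planted driver genes.

    Each of the seven sampled phenotypes is baseline + scale * (sum of
    coupling * standardized driver-gene logCPM + N(0, noise_sd)); grip
    strength is the mean of three noisy trials; the muscle-to-fat ratio is
    computed from the sampled masses.  Body weight is drawn per group
    (Mature lighter than aged groups) so per-100 g normalization is
    non-trivial.
    """
    from .diffexpr import log_cpm

    for ph, drivers in truth.phenotype_drivers.items():
        for gid in drivers:
            if gid not in counts.gene_ids:
                raise ValidationError(f"unknown phenotype driver gene {gid!r}")

    rng = _rng(config, "phenotypes")
    lcpm, _ = log_cpm(counts, factors=None, prior_count=2.0)
    n = counts.n_samples
    z = {}
    for ph, drivers in truth.phenotype_drivers.items():
        sig = np.zeros(n)
        for gid, coupling in drivers.items():
            v = lcpm.loc[gid].to_numpy()
            sd = v.std()
            sig += coupling * ((v - v.mean()) / sd if sd > 0 else np.zeros(n))
        z[ph] = sig

    noise = config.phenotype_noise_sd
    rows: dict[str, np.ndarray | list] = {
        "sample_id": list(counts.sample_ids),
        "group": [counts.groups[s] for s in counts.sample_ids],
    }
    bw = np.array(
        [_BODY_WEIGHT_BASE.get(g, 36.0) for g in rows["group"]]
    ) + _BODY_WEIGHT_SD * noise * rng.normal(size=n)
    rows["body_weight"] = np.maximum(bw, 1e-6)
    for ph, (baseline, scale) in _PHENOTYPE_BASELINES.items():
        signal = z.get(ph, np.zeros(n))
        if ph == "grip_strength":
            trials = [
                baseline + scale * (signal + noise * rng.normal(size=n)) for _ in range(3)
            ]
            val = np.mean(trials, axis=0)
        else:
            val = baseline + scale * (signal + noise * rng.normal(size=n))
        rows[ph] = np.maximum(val, 1e-6)
    rows["muscle_fat_ratio"] = rows["total_muscle"] / rows["total_fat"]
    df = pd.DataFrame(rows)
    cols = ["sample_id", "group", "body_weight",
            "quadriceps_w", "tibialis_anterior_w", "gastrocnemius_w",
            "hindlimb_thickness", "total_muscle", "total_fat",
            "muscle_fat_ratio", "grip_strength"]
    return validate_phenotypes(df[cols])


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Counts, phenotypes and truth in one call."""
    cm, truth = simulate_counts(config)
    phen = simulate_phenotypes(cm, truth, config)
    return cm, phen, truth
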