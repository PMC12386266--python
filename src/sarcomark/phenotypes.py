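"""Gene–phenotype Pearson correlation, per 100 g body weight.

Each mass/thickness/strength phenotype is normalized to 100 g of body
weight before correlating; the muscle-to-fat ratio is a ratio of two
normalized quantities, so normalization cancels and the raw ratio is used.
Correlations are pooled over all samples (all five groups on one regression
line), and the linear-regression parameters needed to draw the fit and its
95% confidence band are emitted alongside r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import NORMALIZED_PHENOTYPES, PHENOTYPE_COLUMNS, ValidationError


def normalize_per_100g(value, body_weight):
    """value x 100 / body weight; nonpositive body weight is a hard error."""
    value = np.asarray(value, dtype=float)
    bw = np.asarray(body_weight, dtype=float)
    if (bw <= 0).any():
        raise ValidationError("body weight must be strictly positive")
    return value * 100.0 / bw


def normalized_phenotype_vector(phenotypes: pd.DataFrame, name: str) -> np.ndarray:
    """One phenotype column, per-100 g normalized where applicable."""
    if name not in PHENOTYPE_COLUMNS:
        raise ValidationError(f"unknown phenotype {name!r}")
    v = phenotypes[name].to_numpy(dtype=float)
    if name in NORMALIZED_PHENOTYPES:
        return normalize_per_100g(v, phenotypes["body_weight"].to_numpy(dtype=float))
    return v


def gene_phenotype_correlations(
    logcpm: pd.DataFrame,
    phenotypes: pd.DataFrame,
    gene_ids: list[str] | None = None,
    phenotype_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r per (gene, phenotype) pair plus regression-line parameters.

    Returns one row per pair with columns gene_id, phenotype, r, slope,
    intercept, n, x_mean, s_xx, resid_sd (the last three parameterize the
    95% CI band of the regression line: half-width at x0 is
    t_{0.975,n-2} * resid_sd * sqrt(1/n + (x0 - x_mean)^2 / s_xx)).
    Zero-variance inputs give r = 0 with ``zero_variance = True``.
    """
    gene_ids = list(logcpm.index) if gene_ids is None else list(gene_ids)
    phenotype_names = (
        list(PHENOTYPE_COLUMNS) if phenotype_names is None else list(phenotype_names)
    )
    missing = [g for g in gene_ids if g not in logcpm.index]
    if missing:
        raise ValidationError(f"gene(s) not in logCPM matrix: {', '.join(missing[:5])}")
    ph = phenotypes.set_index("sample_id").loc[list(logcpm.columns)].reset_index()
    n = len(ph)
    rows = []
    for name in phenotype_names:
        y = normalized_phenotype_vector(ph, name)
        for gid in gene_ids:
            x = logcpm.loc[gid].to_numpy(dtype=float)
            zero_var = x.std() == 0 or y.std() == 0
            if zero_var:
                r, slope, intercept, resid_sd = 0.0, 0.0, float(np.mean(y)), 0.0
                x_mean, s_xx = float(np.mean(x)), 0.0
            else:
                res = stats.linregress(x, y)
                r, slope, intercept = float(res.rvalue), float(res.slope), float(res.intercept)
                x_mean = float(np.mean(x))
                s_xx = float(np.sum((x - x_mean) ** 2))
                resid = y - (slope * x + intercept)
                resid_sd = float(np.sqrt(np.sum(resid**2) / max(n - 2, 1)))
            rows.append(
                {
                    "gene_id": gid,
                    "phenotype": name,
                    "r": r,
                    "slope": slope,
                    "intercept": intercept,
                    "n": n,
                    "x_mean": x_mean,
                    "s_xx": s_xx,
                    "resid_sd": resid_sd,
                    "zero_variance": zero_var,
                }
            )
    return pd.DataFrame(rows)
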