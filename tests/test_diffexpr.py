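import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sarcomark as sm
from sarcomark.diffexpr import fit_nb_glm
from sarcomark.io import ValidationError


# ---------------------------------------------------------------------------
# independent straight-line TMM oracle (no shared code with the package
# beyond scipy.rankdata): direct transcription of the trimmed weighted-mean
# formula, one pair of samples at a time
# ---------------------------------------------------------------------------

def tmm_oracle(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0).astype(float)
    f75 = np.array([np.quantile(counts[:, s] / lib[s], 0.75) for s in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = []
    for s in range(counts.shape[1]):
        ys, yr = counts[:, s].astype(float), counts[:, ref].astype(float)
        keep0 = (ys > 0) & (yr > 0)
        ys, yr = ys[keep0], yr[keep0]
        m = np.log2((ys / lib[s]) / (yr / lib[ref]))
        a = 0.5 * np.log2((ys / lib[s]) * (yr / lib[ref]))
        w = (lib[s] - ys) / (lib[s] * ys) + (lib[ref] - yr) / (lib[ref] * yr)
        if m.size == 0 or np.max(np.abs(m)) < 1e-6:
            logf.append(0.0)
            continue
        n = m.size
        lo_m, lo_a = np.floor(n * 0.3) + 1, np.floor(n * 0.05) + 1
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
        logf.append(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]) if keep.any() else 0.0)
    f = 2.0 ** np.asarray(logf)
    return f / np.exp(np.mean(np.log(f)))


def _as_cm(arr, groups=None):
    arr = np.asarray(arr)
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                      columns=[f"s{j}" for j in range(arr.shape[1])])
    if groups is None:
        groups = ["X"] * arr.shape[1]
    return sm.CountMatrix(df, pd.Series(groups, index=df.columns))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        cm = _as_cm(np.tile([[10], [200], [3000]], (1, 2)))
        np.testing.assert_allclose(sm.tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        a = np.array([10, 200, 3000, 50, 7, 400])
        cm = _as_cm(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(sm.tmm_factors(cm).factors, 1.0, atol=1e-12)

    def test_matches_straight_line_oracle_on_biased_sample(self):
        # one composition-biased sample: a dominant gene inflates s2
        y = np.array(
            [[100, 100, 2000], [50, 55, 52], [200, 210, 190],
             [80, 75, 85], [10, 12, 11], [300, 290, 310]]
        )
        got = sm.tmm_factors(_as_cm(y)).factors.to_numpy()
        np.testing.assert_allclose(got, tmm_oracle(y), atol=1e-8, rtol=0)

    def test_invariant_to_gene_permutation(self, small_dataset):
        _, cm, _, _ = small_dataset
        base = sm.tmm_factors(cm).factors.to_numpy()
        rng = np.random.default_rng(5)
        perm = rng.permutation(cm.n_genes)
        shuffled = sm.CountMatrix(cm.counts.iloc[perm], cm.groups)
        np.testing.assert_allclose(sm.tmm_factors(shuffled).factors, base, atol=1e-12)
        assert abs(np.exp(np.mean(np.log(base))) - 1.0) < 1e-12

    def test_zero_library_is_hard_error(self):
        with pytest.raises(ValidationError, match="zero total"):
            sm.tmm_factors(_as_cm(np.array([[1, 0], [2, 0]])))


class TestLogCPM:
    def test_direct_formula_value(self):
        cm = _as_cm(np.array([[998, 998]]))
        # library sizes forced via explicit factors
        f = sm.NormFactors(
            factors=pd.Series([1.0, 1.0], index=cm.sample_ids),
            lib_sizes=pd.Series([1e6, 1e6], index=cm.sample_ids),
        )
        lcpm, avg = sm.log_cpm(cm, f, prior_count=2.0)
        expected = np.log2(1000 * 1e6 / 1000004)  # = 9.965779 (~9.9658)
        assert abs(lcpm.iloc[0, 0] - expected) < 1e-9
        assert abs(expected - 9.9658) < 1e-4
        assert abs(avg.iloc[0] - expected) < 1e-9

    def test_zero_count_is_finite(self):
        cm = _as_cm(np.array([[0, 0], [100, 120]]))
        lcpm, _ = sm.log_cpm(cm)
        assert np.isfinite(lcpm.to_numpy()).all()

    def test_depth_doubling_near_invariance(self, small_dataset):
        # the prior count is scaled to the *relative* library size (the
        # field's convention), so logCPM is invariant to depth only up to
        # O(prior/count); at these depths that is < 1e-3
        _, cm, _, _ = small_dataset
        l1, _ = sm.log_cpm(cm)
        doubled = sm.CountMatrix(cm.counts * 2, cm.groups)
        l2, _ = sm.log_cpm(doubled)
        diff = (l1 - l2).abs().to_numpy()
        # elementwise bound ~ prior / (count * ln 2)
        bound = 2.0 * 2.0 / (np.maximum(cm.counts.to_numpy(), 1) * np.log(2))
        assert (diff <= bound + 1e-9).all()
        high = (cm.counts.to_numpy() >= 5000)
        assert diff[high].max() < 1e-3


class TestNBGLM:
    def test_matches_statsmodels_glm(self):
        """Dual route: vectorized IRLS vs statsmodels NegativeBinomial GLM."""
        import statsmodels.api as smapi

        rng = np.random.default_rng(3)
        n, G = 10, 12
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
        offset = np.log(rng.uniform(0.8e6, 1.2e6, n))
        y = rng.negative_binomial(5, 0.01, size=(G, n)).astype(float)
        beta, _, _ = fit_nb_glm(y, X, offset, 0.2)
        for g in range(G):
            ref = smapi.GLM(
                y[g], X, family=smapi.families.NegativeBinomial(alpha=0.2), offset=offset
            ).fit(tol=1e-12)
            np.testing.assert_allclose(beta[g], ref.params, atol=1e-6, rtol=0)

    def test_rank_deficient_design_rejected(self):
        y = np.ones((2, 4))
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValidationError, match="full rank"):
            fit_nb_glm(y, X, np.zeros(4), 0.1)


class TestDispersion:
    def test_poisson_data_gives_near_zero_dispersion(self):
        cfg = sm.SimulationConfig(
            n_genes=2000, group_sizes={"Mature": 6, "Middle": 6},
            dispersion=1e-5, seed=4,
        )
        cm, _ = sm.simulate_counts(cfg)
        f = sm.tmm_factors(cm)
        common, _ = sm.estimate_dispersion(cm, f)
        assert common < 0.05

    def test_nb_dispersion_recovered(self):
        commons = []
        for seed in range(11):
            cfg = sm.SimulationConfig(
                n_genes=2000, group_sizes={"Mature": 6, "Middle": 6},
                dispersion=0.4, frac_aging_genes=0.0, seed=seed,
            )
            cm, _ = sm.simulate_counts(cfg)
            f = sm.tmm_factors(cm)
            common, _ = sm.estimate_dispersion(cm, f)
            commons.append(common)
        assert 0.3 <= np.median(commons) <= 0.5

    def test_tagwise_shrinks_between_mle_and_common(self, small_dataset):
        _, cm, _, _ = small_dataset
        f = sm.tmm_factors(cm)
        common, shrunk = sm.estimate_dispersion(cm, f, prior_df=10.0)
        _, unshrunk = sm.estimate_dispersion(cm, f, prior_df=0.0)
        # shrinkage moves every tagwise estimate from its own MLE toward the
        # common value (allow grid-resolution slack)
        lo = np.minimum(unshrunk, common) / 1.1
        hi = np.maximum(unshrunk, common) * 1.1
        inside = (shrunk >= lo) & (shrunk <= hi)
        assert inside.mean() > 0.95


class TestDETest:
    def test_identical_groups_null_identity(self):
        row = np.array([50, 50, 50, 50, 50, 50])
        other = np.array([10, 10, 10, 10, 10, 10])
        cm = _as_cm(np.vstack([row, other]), groups=["A"] * 3 + ["B"] * 3)
        f = sm.tmm_factors(cm)
        res = sm.de_test(cm, f, 0.1, ("A", "B"))
        assert np.allclose(res["logFC"], 0.0, atol=1e-6)
        assert np.allclose(res["p_value"], 1.0, atol=1e-6)

    def test_logfc_sign_flips_with_contrast_order(self, small_dataset, small_de):
        _, cm, _, _ = small_dataset
        factors, _, tagwise, de_aging, _ = small_de
        rev = sm.de_test(cm, factors, tagwise, ("Mature", "Middle"))
        merged = de_aging.merge(rev, on="gene_id", suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["logFC_f"], -merged["logFC_r"], atol=1e-5)
        np.testing.assert_allclose(merged["p_value_f"], merged["p_value_r"], atol=1e-6)

    def test_all_zero_rows_filtered_not_nan(self):
        y = np.array([[0, 0, 0, 0], [10, 12, 9, 11], [100, 90, 110, 95]])
        cm = _as_cm(y, groups=["A", "A", "B", "B"])
        f = sm.tmm_factors(cm)
        res = sm.de_test(cm, f, 0.1, ("A", "B"))
        assert res.attrs["filtered_genes"] == ["g0"]
        assert len(res) == 2 and res.notna().all().all()

    def test_too_small_group_rejected(self, small_dataset, small_de):
        _, cm, _, _ = small_dataset
        factors = small_de[0]
        solo = cm.groups.copy()
        solo.iloc[0] = "Lonely"
        cm2 = sm.CountMatrix(cm.counts, solo)
        with pytest.raises(ValidationError, match="Lonely"):
            sm.de_test(cm2, factors, 0.1, ("Lonely", "Middle"))


class TestBH:
    def test_hand_computed_stepup(self):
        got = sm.bh_fdr([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.008, 0.02, 0.04, 0.04], atol=1e-12)

    def test_all_ones(self):
        np.testing.assert_array_equal(sm.bh_fdr([1.0] * 5), np.ones(5))

    def test_single_p_identity(self):
        np.testing.assert_allclose(sm.bh_fdr([0.03]), [0.03])

    def test_nan_rejected(self):
        with pytest.raises(ValidationError, match="NaN"):
            sm.bh_fdr([0.1, np.nan])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        adj = sm.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert ((adj >= 0) & (adj <= 1)).all()
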