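import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sarcomark as sm
from sarcomark import io as sio
from sarcomark.io import ValidationError
from sarcomark.simulate import SyntheticTruth


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 5},
            {"group_sizes": {"Mature": 1, "Middle": 6}},
            {"frac_aging_genes": 1.2},
            {"dispersion": 0.0},
            {"lib_size_cv": -0.1},
        ],
    )
    def test_degenerate_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sm.SimulationConfig(**kwargs)


class TestCounts:
    def test_planted_count_is_deterministic_from_fraction(self):
        cfg = sm.SimulationConfig(n_genes=1000, frac_aging_genes=0.1, seed=0)
        _, truth = sm.simulate_counts(cfg)
        assert len(truth.aging_genes) == 100

    def test_seeded_determinism_bitwise(self, tmp_path):
        cfg = sm.SimulationConfig(n_genes=120, seed=42)
        for run in ("a", "b"):
            cm, phen, truth = sm.simulate_dataset(cfg)
            sio.write_counts(cm, tmp_path / f"c_{run}.tsv", tmp_path / f"g_{run}.tsv")
            sio.write_phenotypes(phen, tmp_path / f"p_{run}.csv")
            truth.to_json(tmp_path / f"t_{run}.json")
        for stem in ("c", "g", "p", "t"):
            ext = {"c": "tsv", "g": "tsv", "p": "csv", "t": "json"}[stem]
            assert (tmp_path / f"{stem}_a.{ext}").read_bytes() == (
                tmp_path / f"{stem}_b.{ext}"
            ).read_bytes()

    def test_shape_and_dtype(self, small_dataset):
        cfg, cm, _, truth = small_dataset
        assert cm.n_samples == sum(cfg.group_sizes.values())
        assert np.issubdtype(cm.counts.to_numpy().dtype, np.integer)
        assert (cm.counts.to_numpy() >= 0).all()

    def test_planted_logfc_shifts_group_means(self):
        """Sample-mean log2 ratio over planted up-genes recovers the planted
        magnitude (oracle: ratio of group count means, large groups)."""
        est = []
        for seed in range(50):
            cfg = sm.SimulationConfig(
                n_genes=400, frac_aging_genes=0.5, aging_lfc_magnitude=1.0,
                group_sizes={"Mature": 20, "Middle": 20}, seed=seed,
            )
            cm, truth = sm.simulate_counts(cfg)
            up = [g for g, l in truth.aging_lfc.items() if l > 0]
            mat = cm.counts[cm.samples_in("Mature")].mean(axis=1)
            mid = cm.counts[cm.samples_in("Middle")].mean(axis=1)
            est.append(np.log2(mid.loc[up] / mat.loc[up]).mean())
        assert abs(np.mean(est) - 1.0) < 0.15

    def test_reversal_genes_oppose_aging_direction(self, small_dataset):
        _, _, _, truth = small_dataset
        for intervention, revs in truth.reversal_lfc.items():
            assert set(revs) <= truth.aging_genes
            for g, lfc in revs.items():
                assert lfc * truth.aging_lfc[g] < 0

    def test_truth_invariant_enforced(self):
        with pytest.raises(ValidationError, match="oppose"):
            SyntheticTruth(aging_lfc={"g": 1.0}, reversal_lfc={"ALL": {"g": 0.5}})
        with pytest.raises(ValidationError, match="not in aging"):
            SyntheticTruth(aging_lfc={"g": 1.0}, reversal_lfc={"ALL": {"h": -0.5}})

    def test_library_size_cv_calibrated(self):
        """Empirical column-sum CV matches lib_size_cv within 3 SE (50 seeds)."""
        cvs = []
        for seed in range(50):
            cfg = sm.SimulationConfig(
                n_genes=2000, frac_aging_genes=0.0, lib_size_cv=0.1, seed=seed
            )
            cm, _ = sm.simulate_counts(cfg)
            lib = cm.library_sizes().to_numpy(dtype=float)
            cvs.append(lib.std(ddof=1) / lib.mean())
        se = np.std(cvs, ddof=1) / np.sqrt(len(cvs))
        assert abs(np.mean(cvs) - 0.1) < 3 * se

    def test_null_genes_logfc_centered_at_zero(self):
        cfg = sm.SimulationConfig(n_genes=5000, frac_aging_genes=0.1, seed=9)
        cm, truth = sm.simulate_counts(cfg)
        null = [g for g in cm.gene_ids if g not in truth.aging_genes]
        # library-size-normalized group means (raw means would be confounded
        # by the random depth difference between the two groups)
        cpm = cm.counts / cm.library_sizes() * 1e6
        mat = cpm[cm.samples_in("Mature")].mean(axis=1) + 0.5
        mid = cpm[cm.samples_in("Middle")].mean(axis=1) + 0.5
        assert abs(np.log2(mid.loc[null] / mat.loc[null]).mean()) < 0.05


class TestPhenotypes:
    def test_no_signal_no_noise_is_constant(self):
        cfg = sm.SimulationConfig(n_genes=60, phenotype_noise_sd=0.0, seed=2)
        cm, truth = sm.simulate_counts(cfg)
        truth.phenotype_drivers = {ph: {} for ph in truth.phenotype_drivers}
        phen = sm.simulate_phenotypes(cm, truth, cfg)
        for col in sio.PHENOTYPE_COLUMNS:
            assert phen[col].nunique() == 1

    def test_noiseless_single_driver_gives_r_one(self):
        cfg = sm.SimulationConfig(n_genes=60, phenotype_noise_sd=0.0, seed=3)
        cm, truth = sm.simulate_counts(cfg)
        gid = cm.gene_ids[7]
        truth.phenotype_drivers = {"total_muscle": {gid: 2.0}}
        phen = sm.simulate_phenotypes(cm, truth, cfg)
        lcpm, _ = sm.log_cpm(cm)
        r = stats.pearsonr(lcpm.loc[gid], phen["total_muscle"]).statistic
        assert abs(r - 1.0) < 1e-9

    def test_noisy_driver_matches_closed_form_r(self):
        """coupling 1, noise 1 -> population r = 1/sqrt(2) ~ 0.707."""
        rs = []
        for seed in range(100):
            cfg = sm.SimulationConfig(n_genes=60, phenotype_noise_sd=1.0, seed=seed)
            cm, truth = sm.simulate_counts(cfg)
            gid = cm.gene_ids[0]
            truth.phenotype_drivers = {"total_muscle": {gid: 1.0}}
            phen = sm.simulate_phenotypes(cm, truth, cfg)
            lcpm, _ = sm.log_cpm(cm)
            rs.append(stats.pearsonr(lcpm.loc[gid], phen["total_muscle"]).statistic)
        assert abs(np.mean(rs) - 1.0 / np.sqrt(2)) < 0.05

    def test_unknown_driver_gene_rejected(self, small_dataset):
        cfg, cm, _, truth = small_dataset
        bad = SyntheticTruth(
            aging_lfc=dict(truth.aging_lfc),
            reversal_lfc={k: dict(v) for k, v in truth.reversal_lfc.items()},
            phenotype_drivers={"total_muscle": {"nope": 1.0}},
        )
        with pytest.raises(ValidationError, match="nope"):
            sm.simulate_phenotypes(cm, bad, cfg)

    def test_ratio_identity_and_one_row_per_sample(self, small_dataset):
        _, cm, phen, _ = small_dataset
        assert list(phen["sample_id"]) == list(cm.sample_ids)
        np.testing.assert_allclose(
            phen["muscle_fat_ratio"], phen["total_muscle"] / phen["total_fat"],
            atol=1e-12, rtol=0,
        )

    def test_mature_mice_are_lighter(self, small_dataset):
        _, _, phen, _ = small_dataset
        by_group = phen.groupby("group")["body_weight"].mean()
        assert by_group["Mature"] < by_group["Middle"]
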