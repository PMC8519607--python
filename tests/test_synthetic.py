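"""Calibration and determinism of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from teanet import (
    DamSpec,
    HubSpec,
    ModuleSpec,
    SyntheticConfig,
    generate_cohort,
    make_correlated_block,
    plant_hub_gene,
)
from teanet.errors import ParameterError

from conftest import small_config


class TestCorrelatedBlock:
    def test_near_unit_target_gives_identical_columns(self):
        block = make_correlated_block(50, 4, 1 - 1e-9, rng_seed=0)
        corr = np.corrcoef(block.T)
        assert np.allclose(corr, 1.0, atol=1e-4)

    def test_monte_carlo_mean_correlation_matches_target(self):
        # 500 independent blocks at the study size: mean off-diagonal sample
        # PCC must sit within +/-0.03 of the latent correlation 0.9
        means = []
        for seed in range(500):
            block = make_correlated_block(68, 7, 0.9, rng_seed=seed)
            corr = np.corrcoef(block.T)
            means.append(corr[np.triu_indices(7, 1)].mean())
        assert abs(np.mean(means) - 0.9) < 0.03

    def test_large_sample_convergence(self):
        block = make_correlated_block(10_000, 2, 0.5, rng_seed=42)
        r = np.corrcoef(block.T)[0, 1]
        assert 0.47 <= r <= 0.53

    @pytest.mark.parametrize("bad_r", [0.0, 1.0, -0.2, 1.5])
    def test_target_r_outside_open_interval_rejected(self, bad_r):
        with pytest.raises(ParameterError):
            make_correlated_block(10, 3, bad_r, rng_seed=0)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ParameterError):
            make_correlated_block(10, 1, 0.5, rng_seed=0)
        with pytest.raises(ParameterError):
            make_correlated_block(2, 3, 0.5, rng_seed=0)


class TestGenerateCohort:
    def test_same_seed_is_byte_identical(self):
        m1, e1, t1 = generate_cohort(small_config(seed=5))
        m2, e2, t2 = generate_cohort(small_config(seed=5))
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert t1.group_labels.equals(t2.group_labels)

    def test_different_seed_differs(self):
        m1, _, _ = generate_cohort(small_config(seed=5))
        m2, _, _ = generate_cohort(small_config(seed=6))
        assert not np.allclose(m1.values, m2.values)

    def test_abundances_strictly_positive(self, cohort):
        metab, _, _ = cohort
        assert (metab.values.to_numpy() > 0).all()

    def test_zero_qc_cv_gives_identical_qc_rows(self):
        metab, _, _ = generate_cohort(small_config(qc_cv=0.0, n_qc=3))
        qc = metab.qc().to_numpy()
        assert np.array_equal(qc[0], qc[1]) and np.array_equal(qc[1], qc[2])
        assert np.allclose(np.corrcoef(np.log10(qc)), 1.0)

    def test_planted_log2_effect_yields_fourfold_geometric_ratio(self):
        # mean over 200 seeds of the group geometric-mean ratio for a planted
        # log2 effect of 2 must land in [3.5, 4.5]; a fixed modest feature
        # spread keeps the ratio estimator well-behaved at n = 10/group
        ratios = []
        for seed in range(200):
            cfg = small_config(
                n_accessions=20,
                n_groups=2,
                feature_log_sd=0.1,
                dam_specs=[DamSpec("aa001", 1, 2, 2.0)],
                seed=seed,
            )
            metab, _, truth = generate_cohort(cfg)
            bio = metab.biological()["aa001"]
            ga = bio[truth.group_labels == 1]
            gb = bio[truth.group_labels == 2]
            gm = lambda x: np.exp(np.mean(np.log(x)))
            ratios.append(gm(ga) / gm(gb))
        assert 3.5 <= np.mean(ratios) <= 4.5

    def test_group_sizes_must_sum(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_accessions=10, n_groups=2, group_sizes=[5, 6])

    def test_module_sets_must_be_disjoint(self):
        with pytest.raises(ParameterError):
            small_config(
                modules=[
                    ModuleSpec(("aa001", "aa002"), 0.5),
                    ModuleSpec(("aa002", "aa003"), 0.5),
                ]
            )

    def test_variability_regimes_separate(self):
        # features from the wide-spread regime must show far larger fold
        # ranges than the narrow "primary-like" regime
        metab, _, _ = generate_cohort(SyntheticConfig(n_features=100, seed=3))
        bio = metab.biological()
        fold = bio.max(axis=0) / bio.min(axis=0)
        regime = metab.feature_meta["regime"]
        assert fold[regime == "secondary-like"].median() > 5 * fold[regime == "primary-like"].median()


class TestPlantHubGene:
    @staticmethod
    def _module_cohort(seed, k=25, module_r=0.4):
        cfg = small_config(
            n_accessions=68,
            n_features=40,
            modules=[ModuleSpec(tuple(f"aa{i:03d}" for i in range(1, k + 1)), module_r)],
            seed=seed,
        )
        return generate_cohort(cfg)

    def test_single_target_near_unit_r_tracks_metabolite(self):
        metab, expr, _ = self._module_cohort(0)
        planted = plant_hub_gene(expr, metab, ["aa030"], 1 - 1e-6, rng_seed=1)
        r = np.corrcoef(
            np.log10(planted.values["HUB0001"]), np.log10(metab.biological()["aa030"])
        )[0, 1]
        assert r > 0.999

    def test_monte_carlo_mean_target_correlation(self):
        # gene planted at r = 0.6 against a 25-member correlated module:
        # mean gene-target sample PCC over 200 seeds within +/-0.05 of 0.6
        targets = [f"aa{i:03d}" for i in range(1, 26)]
        means = []
        for seed in range(200):
            metab, expr, _ = self._module_cohort(seed)
            planted = plant_hub_gene(expr, metab, targets, 0.6, rng_seed=seed + 10_000)
            g = np.log10(planted.values["HUB0001"])
            cols = np.log10(metab.biological()[targets])
            rs = [np.corrcoef(g, cols[t])[0, 1] for t in targets]
            means.append(np.mean(rs))
        assert abs(np.mean(means) - 0.6) < 0.05

    def test_empty_target_list_rejected(self):
        metab, expr, _ = self._module_cohort(0)
        with pytest.raises(ParameterError):
            plant_hub_gene(expr, metab, [], 0.5, rng_seed=0)

    def test_unknown_feature_rejected(self):
        metab, expr, _ = self._module_cohort(0)
        with pytest.raises(KeyError):
            plant_hub_gene(expr, metab, ["nope01"], 0.5, rng_seed=0)
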