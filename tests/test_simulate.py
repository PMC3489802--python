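"""Synthetic-cohort generator contracts: reproducibility, carriers, survival."""

import numpy as np
import pandas as pd
import pytest

from rarseek.simulate import (CohortConfig, ImplantSpec, InteractionSpec,
                              build_probe_map, default_config, simulate_cohort)


def _one_gain(freq=0.5, hazard=1.0):
    return ImplantSpec("G", "16", 5_000_000, 15_000_000, "gain",
                       carrier_freq_stageI=freq, carrier_freq_stageII=freq,
                       hazard_multiplier=hazard)


class TestConfigValidation:
    def test_mean_sign_must_match_type(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ImplantSpec("bad", "1", 1, 100, "gain", mean_log2=-0.4)

    def test_default_means_by_type(self):
        assert ImplantSpec("g", "1", 1, 100, "gain").mean_log2 == 0.58
        assert ImplantSpec("l", "1", 1, 100, "loss").mean_log2 == -1.0
        assert ImplantSpec("a", "1", 1, 100, "amplification").mean_log2 == 1.8
        assert ImplantSpec("h", "1", 1, 100, "homozygous_deletion").mean_log2 == -1.8

    def test_stage_count_bounds(self):
        with pytest.raises(ValueError):
            CohortConfig(n_samples=10, n_stageI=11)

    def test_opposite_sign_overlap_in_same_carrier_rejected(self):
        gain = _one_gain(freq=1.0)
        loss = ImplantSpec("L", "16", 10_000_000, 20_000_000, "loss",
                           carrier_freq_stageI=1.0, carrier_freq_stageII=1.0)
        cfg = CohortConfig(n_samples=8, n_stageI=2, implants=(gain, loss),
                           chromosomes=("16",), seed=0)
        with pytest.raises(ValueError, match="opposite sign"):
            simulate_cohort(cfg)


class TestProbeMapLayout:
    def test_probe_density_is_preserved_under_chromosome_subsets(self):
        full = build_probe_map(24_107)
        sub = build_probe_map(24_107, chromosomes=("17",))
        full_17 = full.chrom_slices()["17"]
        assert len(sub) == full_17.stop - full_17.start
        spacing = np.diff(sub.position)
        assert spacing.max() < 1_000_000  # no artificial run-breaking gaps

    def test_positions_strictly_increasing_within_chromosome(self):
        pm = build_probe_map(5_000)
        for sl in pm.chrom_slices().values():
            assert np.all(np.diff(pm.position[sl]) > 0)


class TestSimulateCohort:
    def test_same_seed_identical_outputs(self):
        cfg = default_config(seed=3, chromosomes=("16", "17"))
        p1, m1, c1, t1 = simulate_cohort(cfg)
        p2, m2, c2, t2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(c1.data, c2.data)
        pd.testing.assert_frame_equal(t1.carriers, t2.carriers)

    def test_zero_noise_exact_quota_plateau(self):
        cfg = CohortConfig(n_samples=48, n_stageI=12, noise_sd=0.0,
                           carrier_mode="exact", implants=(_one_gain(0.5),),
                           chromosomes=("16",), seed=1)
        probes, matrix, _c, truth = simulate_cohort(cfg)
        first, last = truth.implant_probes["G"]
        carriers = truth.carriers["G"].to_numpy(dtype=bool)
        assert carriers.sum() == 24  # exact quota at freq 0.5
        inside = matrix.values[:, first:last + 1]
        outside = np.delete(matrix.values, np.s_[first:last + 1], axis=1)
        assert np.all(inside[carriers] == 0.58)
        assert np.all(inside[~carriers] == 0.0)
        assert np.all(outside == 0.0)

    def test_binomial_carrier_frequency_calibration(self):
        """Empirical carrier frequency of a 0.5 implant stays within +-0.15
        (binomial SE at n=48 is 0.072) in the large majority of replicates."""
        within = 0
        reps = 40
        for seed in range(reps):
            cfg = CohortConfig(n_samples=48, n_stageI=12,
                               implants=(_one_gain(0.5),),
                               chromosomes=("16",), seed=seed)
            _p, _m, _c, truth = simulate_cohort(cfg)
            within += abs(truth.carriers["G"].mean() - 0.5) <= 0.15
        assert within >= int(0.9 * reps)

    def test_null_hazard_gives_exchangeable_survival(self):
        """hazard_multiplier 1: carrier survival differs only by sampling noise
        (log-rank p roughly uniform over replicates)."""
        from rarseek.clinical import logrank_test

        pvals = []
        for seed in range(30):
            cfg = CohortConfig(n_samples=60, n_stageI=15,
                               implants=(_one_gain(0.5, hazard=1.0),),
                               chromosomes=("16",), seed=seed)
            _p, _m, clinical, truth = simulate_cohort(cfg)
            carriers = truth.carriers["G"].to_numpy()
            if carriers.sum() in (0, 60):
                continue
            _s, p = logrank_test(clinical.data["survival_years"],
                                 clinical.data["event"], carriers)
            pvals.append(p)
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() < 0.2
        assert pvals.mean() > 0.3

    def test_interaction_hazard_only_for_joint_carriers(self):
        a = _one_gain(1.0)
        b = ImplantSpec("H", "17", 30_000_000, 40_000_000, "gain",
                        carrier_freq_stageI=0.0, carrier_freq_stageII=0.0)
        cfg = CohortConfig(n_samples=20, n_stageI=5, implants=(a, b),
                           interactions=(InteractionSpec(("G", "H"), 8.0),),
                           chromosomes=("16", "17"), seed=2)
        _p, _m, _c, truth = simulate_cohort(cfg)
        # nobody carries H, so the interaction multiplier never applies
        assert np.allclose(truth.hazard, cfg.baseline_hazard)

    def test_stage_stratified_frequencies(self):
        imp = ImplantSpec("G", "16", 5_000_000, 15_000_000, "gain",
                          carrier_freq_stageI=0.0, carrier_freq_stageII=1.0)
        cfg = CohortConfig(n_samples=40, n_stageI=10, implants=(imp,),
                           carrier_mode="exact", chromosomes=("16",), seed=3)
        _p, _m, _c, truth = simulate_cohort(cfg)
        assert truth.carriers.loc[truth.stage == "I", "G"].sum() == 0
        assert truth.carriers.loc[truth.stage == "II", "G"].sum() == 30

    def test_clinical_table_marginals_plausible(self):
        cfg = default_config(seed=4, chromosomes=("16",), n_samples=400,
                             n_stageI=92)
        _p, _m, clinical, _t = simulate_cohort(cfg)
        df = clinical.data
        assert abs((df["er"] == "positive").mean() - 0.521) < 0.08
        assert abs((df["her2"] == "positive").mean() - 0.229) < 0.07
        assert set(df["subtype"]) <= {"LuminalA", "LuminalB", "HER2", "TNBC"}


class TestCoxCoverageProperty:
    def test_configured_hazard_recovered_within_ci(self):
        """Planted single-marker hazard multiplier recovered by the Cox fit:
        the 95% CI covers truth in >= 90% of replicates at n=300."""
        from rarseek.clinical import cox_fit

        covered = 0
        reps = 40
        hr_true = 3.0
        for seed in range(reps):
            cfg = CohortConfig(n_samples=300, n_stageI=75,
                               implants=(_one_gain(0.4, hazard=hr_true),),
                               chromosomes=("16",), seed=seed)
            _p, _m, clinical, truth = simulate_cohort(cfg)
            fit = cox_fit(pd.DataFrame({"m": truth.carriers["G"].to_numpy()}),
                          clinical.data["survival_years"], clinical.data["event"])
            row = fit.cox[0]
            covered += row.ci_low <= hr_true <= row.ci_high
        assert covered >= int(0.875 * reps)
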