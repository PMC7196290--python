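"""Generator contracts: determinism, noise-free limits, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ctctools import (
    SENTINEL,
    SyntheticCohortConfig,
    compute_emt_scores,
    concordance_rate,
    delta_ct,
    generate_ct_matrix,
    generate_ctc_trajectories,
    generate_emt_cells,
    generate_mutation_table,
    generate_survival_cohort,
    impute_undetected,
    relative_expression,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field, value", [
        ("dropout_base_rate", 1.5),
        ("censoring_rate", -0.1),
        ("concordance_target", 2.0),
        ("cells_per_group", 0),
        ("ct_noise_sd", -1.0),
        ("survival_scale", -5.0),
        ("genes", ("EPCAM", "VIM")),  # reference gene missing
    ])
    def test_invalid_rejected(self, field, value):
        cfg = dataclasses.replace(SyntheticCohortConfig(), **{field: value})
        with pytest.raises(ValueError):
            cfg.validate()


class TestCtMatrixGenerator:
    def test_deterministic_under_seed(self, quiet_config):
        a, la = generate_ct_matrix(quiet_config)
        b, lb = generate_ct_matrix(quiet_config)
        pd.testing.assert_frame_equal(a.ct, b.ct)
        pd.testing.assert_frame_equal(a.quality, b.quality)
        pd.testing.assert_series_equal(la, lb)

    def test_noise_free_groups_are_constant(self):
        cfg = SyntheticCohortConfig(ct_noise_sd=1e-15, dropout_base_rate=0.0,
                                    dropout_ct_slope=0.0, cells_per_group=6,
                                    low_quality_fraction=0.0, seed=1)
        m, labels = generate_ct_matrix(cfg)
        for g in labels.unique():
            block = m.ct.loc[:, labels[labels == g].index]
            assert float(block.var(axis=1).max()) == pytest.approx(0.0, abs=1e-20)

    def test_dropout_rate_binomial_oracle(self):
        cfg = SyntheticCohortConfig(
            n_groups=4, cells_per_group=250, include_wbc_group=False,
            dropout_base_rate=0.2, dropout_ct_slope=0.0, seed=5)
        m, _ = generate_ct_matrix(cfg)
        n = m.ct.size
        assert n >= 10_000
        frac = float((m.ct == SENTINEL).to_numpy().mean())
        tol = 3 * np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) <= tol

    def test_wbc_group_expresses_leukocyte_marker_only(self):
        cfg = SyntheticCohortConfig(ct_noise_sd=0.1, dropout_base_rate=0.0,
                                    dropout_ct_slope=0.0, seed=2)
        m, labels = generate_ct_matrix(cfg)
        wbc = labels[labels == "WBC"].index
        rel = relative_expression(delta_ct(impute_undetected(m)))
        assert (rel.values.loc["PTPRC", wbc] > rel.values.loc["EPCAM", wbc]).all()
        tumor = labels[labels != "WBC"].index
        assert (rel.values.loc["PTPRC", tumor] <
                rel.values.loc["PTPRC", wbc].min()).all()


class TestEMTRecovery:
    def test_noise_free_ratio_recovery(self):
        """m_sum = k x e_sum  ->  M-score exactly 100k/(1+k) as noise -> 0."""
        for k in (0.5, 1.94, 4.0):
            m = generate_emt_cells(k, n_cells=10, ct_noise_sd=0.0, seed=0)
            rel = relative_expression(delta_ct(impute_undetected(m)))
            scores = compute_emt_scores(rel)
            assert np.allclose(scores["m_score"], 100 * k / (1 + k), atol=1e-9)


class TestTrajectories:
    def test_noise_free_means_exact_and_pr_floor(self):
        cfg = SyntheticCohortConfig(trajectory_noise_sd=0.0, n_patients=10, seed=3)
        for series, assessments in generate_ctc_trajectories(cfg):
            arm = assessments[0].category
            effect = cfg.response_effect[arm]
            base = series.baseline.count_75
            for d in series.draws[1:]:
                assert 100 * (d.count_75 - base) / base == pytest.approx(effect)
        floor = dataclasses.replace(cfg, response_effect={"PD": 70.1, "PR": -100.0})
        for series, assessments in generate_ctc_trajectories(floor):
            if assessments[0].category == "PR":
                assert all(d.raw_count == 0 for d in series.draws[1:])

    def test_stochastic_counts_are_integers(self, quiet_config):
        for series, _ in generate_ctc_trajectories(quiet_config):
            for d in series.draws:
                assert d.raw_count == int(d.raw_count) >= 0

    def test_monte_carlo_arm_means(self):
        """Empirical arm means stay within 3 SEM of the configured effects."""
        cfg = SyntheticCohortConfig(n_patients=1000, seed=11)
        deltas = {"PD": [], "PR": []}
        for series, assessments in generate_ctc_trajectories(cfg):
            arm = assessments[0].category
            base = series.baseline.count_75
            deltas[arm] += [100 * (d.count_75 - base) / base
                            for d in series.draws[1:]]
        for arm, effect in cfg.response_effect.items():
            arr = np.array(deltas[arm])
            sem = arr.std(ddof=1) / np.sqrt(arr.size)
            assert abs(arr.mean() - effect) <= 3 * sem


class TestSurvivalGenerator:
    def test_fully_censored_boundary(self):
        cfg = SyntheticCohortConfig(censoring_rate=1.0, seed=4)
        recs = generate_survival_cohort(cfg)
        assert all(r.event == 0 for r in recs)

    def test_hazard_ratio_shortens_high_arm(self):
        cfg = SyntheticCohortConfig(n_patients=400, censoring_rate=0.0, seed=6)
        recs = generate_survival_cohort(cfg, true_cutoff=37.0, hazard_ratio=4.0)
        high = [r.time for r in recs if r.baseline_count_75 > 37.0]
        low = [r.time for r in recs if r.baseline_count_75 <= 37.0]
        assert np.median(high) < np.median(low)

    def test_invalid_shape_rejected(self):
        cfg = dataclasses.replace(SyntheticCohortConfig(), survival_shape=-1.0)
        with pytest.raises(ValueError):
            generate_survival_cohort(cfg)


class TestMutationGenerator:
    @pytest.mark.parametrize("target, expected", [(1.0, 100.0), (0.0, 0.0)])
    def test_boundaries(self, target, expected):
        cfg = SyntheticCohortConfig(concordance_target=target, seed=8)
        res = concordance_rate(generate_mutation_table(cfg, n_samples=200))
        assert res.rate == expected

    def test_emergent_pair_inserted(self):
        cfg = SyntheticCohortConfig(seed=9)
        table = generate_mutation_table(cfg, n_samples=5, n_emergent_pairs=1)
        from ctctools import detect_emergent
        events = detect_emergent(table)
        assert len(events) == 1
        assert events[0].locus == "T790M"
        assert events[0].modality == "both"

    def test_concordance_binomial_oracle(self):
        cfg = SyntheticCohortConfig(concordance_target=0.8, seed=10)
        res = concordance_rate(generate_mutation_table(cfg, n_samples=10_000))
        tol = 100 * 3 * np.sqrt(0.8 * 0.2 / 10_000)
        assert abs(res.rate - 80.0) <= tol


def test_generators_are_independent_streams():
    """Calling one generator does not perturb another under the same seed."""
    cfg = SyntheticCohortConfig(cells_per_group=5, n_patients=8, seed=42)
    m1, _ = generate_ct_matrix(cfg)
    generate_mutation_table(cfg)  # interleaved call must not matter
    recs1 = generate_survival_cohort(cfg)
    m2, _ = generate_ct_matrix(cfg)
    recs2 = generate_survival_cohort(cfg)
    pd.testing.assert_frame_equal(m1.ct, m2.ct)
    assert [r.time for r in recs1] == [r.time for r in recs2]
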