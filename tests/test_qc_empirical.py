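import math

import numpy as np
import pandas as pd
import pytest

from telosim import SimParams
from telosim.exceptions import DomainError, FormatError
from telosim.experiments import _paired_sampling
from telosim.qc_empirical import (
    default_plate_means,
    duplicate_ts_icc,
    estimate_error_sigma,
    generate_fixture,
    qc_report,
    read_replicate_table,
    triplicate_mean_sd,
    write_replicate_table,
)


def small_table():
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 4 + ["s1"] * 2,
            "plate_id": ["p1"] * 6,
            "well_id": [f"w{i}" for i in range(6)],
            "target": ["T", "T", "T", "T", "S", "S"],
            "cq": [14.7, 14.8, 14.6, 14.7, 24.6, 24.8],
        }
    )


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        fixture = generate_fixture(n_replicates=24, seed=1)
        path = tmp_path / "reps.csv"
        write_replicate_table(fixture, path)
        back = read_replicate_table(path)
        pd.testing.assert_frame_equal(back, fixture)

    def test_well_formed_table(self, tmp_path):
        path = tmp_path / "t.csv"
        small_table().to_csv(path, index=False)
        assert len(read_replicate_table(path)) == 6

    def test_missing_column(self, tmp_path):
        path = tmp_path / "t.csv"
        small_table().drop(columns="cq").to_csv(path, index=False)
        with pytest.raises(FormatError, match="cq"):
            read_replicate_table(path)

    def test_bad_target_names_row(self, tmp_path):
        table = small_table()
        table.loc[3, "target"] = "X"
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        with pytest.raises(FormatError, match="row 3"):
            read_replicate_table(path)

    def test_non_numeric_cq_names_row(self, tmp_path):
        table = small_table()
        table["cq"] = table["cq"].astype(object)
        table.loc[2, "cq"] = "oops"
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        with pytest.raises(FormatError, match="row 2"):
            read_replicate_table(path)

    def test_duplicate_wells_rejected(self, tmp_path):
        table = small_table()
        table.loc[1, "well_id"] = "w0"
        path = tmp_path / "t.csv"
        table.to_csv(path, index=False)
        with pytest.raises(FormatError, match="duplicate"):
            read_replicate_table(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("")
        with pytest.raises(FormatError):
            read_replicate_table(path)


class TestEstimateErrorSigma:
    def test_identical_replicates_give_zero(self):
        table = small_table()
        table["cq"] = [14.7] * 4 + [24.6] * 2
        est = estimate_error_sigma(table)
        assert est["T"].sigma_pooled == 0.0 and est["T"].sigma_pairwise == 0.0

    def test_two_replicates_hand_value(self):
        # a single pair differing by d has pairwise sigma |d| / sqrt(2)
        d = 0.12
        table = small_table().iloc[4:].copy()
        table["cq"] = [24.6, 24.6 + d]
        est = estimate_error_sigma(table)
        assert est["S"].sigma_pairwise == pytest.approx(d / math.sqrt(2), abs=1e-12)
        assert est["S"].sigma_pooled == pytest.approx(d / math.sqrt(2), abs=1e-12)

    def test_parameter_recovery_from_fixture(self):
        fixture = generate_fixture(
            n_replicates=576, sigma_t_assay=0.053, sigma_s_assay=0.095, seed=3
        )
        est = estimate_error_sigma(fixture)
        assert est["T"].sigma_pooled == pytest.approx(0.053, rel=0.07)
        assert est["S"].sigma_pooled == pytest.approx(0.095, rel=0.07)
        assert est["T"].n_replicates == 576

    def test_pairwise_equals_pooled_for_balanced_data(self, rng):
        rows = []
        for s in range(10):
            for r in range(4):
                rows.append(
                    {
                        "sample_id": f"s{s}",
                        "plate_id": "p1",
                        "well_id": f"w{s}_{r}",
                        "target": "T",
                        "cq": 14.7 + rng.normal(0, 0.05) + 0.1 * s,
                    }
                )
        est = estimate_error_sigma(pd.DataFrame(rows))
        assert est["T"].sigma_pairwise == pytest.approx(est["T"].sigma_pooled, abs=1e-12)

    def test_recovery_is_unbiased_with_expected_precision(self):
        # over 50 seeded fixtures the pooled estimate is unbiased (within
        # 2%) and its spread matches the sqrt(sigma^2 / (2 (N - groups)))
        # large-sample standard error within 20%
        truth = 0.053
        estimates = [
            estimate_error_sigma(
                generate_fixture(n_replicates=576, sigma_t_assay=truth, seed=seed)
            )["T"].sigma_pooled
            for seed in range(50)
        ]
        assert np.mean(estimates) == pytest.approx(truth, rel=0.02)
        asymptotic_se = math.sqrt(truth**2 / (2 * (576 - 1)))
        assert np.std(estimates, ddof=1) == pytest.approx(asymptotic_se, rel=0.20)

    def test_insufficient_replication_lists_samples(self):
        table = small_table()
        table.loc[5, "sample_id"] = "lonely"
        with pytest.raises(DomainError, match="lonely"):
            estimate_error_sigma(table)

    def test_plate_shift_inflates_pooled_sd(self):
        # law of total variance: pooling over shifted plates exceeds the
        # per-plate spread
        fixture = generate_fixture(
            n_replicates=400,
            sigma_s_assay=0.095,
            plate_means=default_plate_means(n_plates=2, shift_s=0.25),
            seed=4,
        )
        est = estimate_error_sigma(fixture)["S"]
        assert est.sigma_pooled > max(est.sigma_per_plate.values())


class TestTriplicateMeans:
    def test_independent_replicates_reduce_by_sqrt3(self):
        fixture = generate_fixture(n_replicates=5760, sigma_t_assay=0.09, seed=5)
        res = triplicate_mean_sd(fixture, group_size=3)["T"]
        assert res.group_mean_sd == pytest.approx(0.09 / math.sqrt(3), rel=0.05)
        assert res.reduction_factor == pytest.approx(math.sqrt(3), rel=0.05)

    def test_group_size_one_is_identity(self):
        fixture = generate_fixture(n_replicates=60, seed=6)
        res = triplicate_mean_sd(fixture, group_size=1)["T"]
        assert res.reduction_factor == pytest.approx(1.0, abs=1e-9)

    def test_plate_shifts_pull_reduction_below_sqrt3(self):
        shifted = generate_fixture(
            n_replicates=5760,
            sigma_s_assay=0.095,
            plate_means=default_plate_means(n_plates=2, shift_s=0.12),
            seed=7,
        )
        res = triplicate_mean_sd(shifted, group_size=3)["S"]
        assert res.reduction_factor < math.sqrt(3) * 0.95

    def test_indivisible_groups_rejected(self):
        fixture = generate_fixture(n_replicates=20, seed=8)
        with pytest.raises(DomainError, match="divisible"):
            triplicate_mean_sd(fixture, group_size=3)


class TestDuplicateTsIcc:
    def test_identical_runs(self):
        ts = np.linspace(0.5, 1.5, 20)
        res = duplicate_ts_icc(ts, ts)
        assert res.icc_result.icc == pytest.approx(1.0, abs=1e-12)
        assert not res.below_benchmark

    @pytest.mark.parametrize(
        ("sigma", "expect_flag"), [(0.05, False), (0.15, True)]
    )
    def test_simulated_duplicate_runs(self, sigma, expect_flag):
        p = SimParams(n=10_000, sigma_eps_t=sigma, sigma_eps_s=sigma, seed=21)
        d1, d2 = _paired_sampling(p, np.random.default_rng(21))
        res = duplicate_ts_icc(d1.mts, d2.mts)
        assert res.below_benchmark is expect_flag
        if sigma == 0.05:
            assert res.icc_result.icc == pytest.approx(0.80, abs=0.03)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            duplicate_ts_icc(np.ones(5), np.ones(4))


class TestFixtureGenerator:
    def test_zero_sigma_reproduces_plate_means(self):
        means = default_plate_means()
        fixture = generate_fixture(
            n_replicates=12, sigma_t_assay=0.0, sigma_s_assay=0.0, plate_means=means, seed=9
        )
        for row in fixture.itertuples():
            assert row.cq == means[row.plate_id][row.target]

    def test_deterministic_given_seed(self):
        a = generate_fixture(n_replicates=48, seed=10)
        b = generate_fixture(n_replicates=48, seed=10)
        pd.testing.assert_frame_equal(a, b)

    def test_qc_report_hides_cv_by_default(self):
        fixture = generate_fixture(n_replicates=48, seed=11)
        report = qc_report(fixture)
        assert "cv_on_cq" not in report["targets"]["T"]
        with_cv = qc_report(fixture, include_cv=True)
        assert "cv_warning" in with_cv["targets"]["T"]
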