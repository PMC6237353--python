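"""Signal-drift correction and the QC RSD benchmark."""

import numpy as np
import pandas as pd
import pytest

from metlab import drift_correct as dc
from metlab.errors import ConfigurationError, ValidationError
from metlab.precision_compare import rsd
from metlab.synthetic_data import DriftSpec, make_drift_table


def single_batch_table(seed=1, n_features=200, n_samples=80, noise=0.05, slope=0.3):
    spec = DriftSpec(slope_range=slope, batch_offsets=(1.0,), noise_cv=noise, seed=seed)
    return make_drift_table(n_features, n_samples, spec, include_is=True)


class TestIsNormalize:
    def _table(self):
        idx = pd.Index([f"s{i}" for i in range(6)], name="sample_id")
        is_col = pd.Series([100.0, 120, 90, 110, 95, 105], index=idx)
        return pd.DataFrame({"f1": is_col, "f2": 2 * is_col, "IS_1": is_col})

    def test_feature_equal_to_is_becomes_constant_at_grand_mean(self):
        t = self._table()
        out = dc.is_normalize(t, {"f1": "IS_1"})
        assert np.allclose(out["f1"], t["IS_1"].mean())
        assert rsd(out["f1"]) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_codrift_removed(self):
        out = dc.is_normalize(self._table(), {"f2": "IS_1"})
        assert np.allclose(out["f2"], out["f2"].iloc[0])

    def test_zero_is_flags_sample_missing(self):
        t = self._table()
        t.loc["s3", "IS_1"] = 0.0
        with pytest.warns(UserWarning, match="s3"):
            out = dc.is_normalize(t, {"f1": "IS_1"})
        assert np.isnan(out.loc["s3", "f1"])
        assert out["f1"].drop("s3").notna().all()

    def test_independent_noise_adds_in_quadrature(self, rng):
        """Corrected RSD ~ sqrt(cv_f^2 + cv_is^2) for independent noise."""
        cv_f, cv_is, n, reps = 0.05, 0.08, 50, 1000
        got = []
        for _ in range(reps):
            idx = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
            t = pd.DataFrame(
                {
                    "f": 1000 * (1 + rng.normal(0, cv_f, n)),
                    "IS_1": 500 * (1 + rng.normal(0, cv_is, n)),
                },
                index=idx,
            )
            got.append(rsd(dc.is_normalize(t, {"f": "IS_1"})["f"]))
        expected = np.sqrt(cv_f**2 + cv_is**2) * 100
        assert np.mean(got) == pytest.approx(expected, rel=0.05)


class TestLinearSequenceFit:
    def test_exact_line_recovered(self):
        orders = np.arange(1, 12)
        m = dc.fit_linear_sequence(100 + 10.0 * (orders - 1), orders)
        assert (m.slope, m.intercept) == (pytest.approx(10.0), pytest.approx(90.0))
        assert m.fit_ok and m.n_qc_used == 11

    def test_constant_values_give_zero_slope(self):
        m = dc.fit_linear_sequence([50.0] * 5, np.arange(5))
        assert m.slope == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = np.arange(1, 21, dtype=float)
        y = 500 + 3.0 * x + rng.normal(0, 5, x.size)
        m = dc.fit_linear_sequence(y, x)
        design = np.column_stack([np.ones_like(x), x])
        b = np.linalg.solve(design.T @ design, design.T @ y)
        assert (m.intercept, m.slope) == (pytest.approx(b[0], rel=1e-10), pytest.approx(b[1], rel=1e-10))

    def test_single_qc_degrades_to_unfit(self):
        m = dc.fit_linear_sequence([100.0], [1])
        assert not m.fit_ok

    def test_parameter_recovery_within_three_standard_errors(self, rng):
        """Generated slopes recovered within 3 SE in >= 99% of features."""
        n_qc, n_feat, sigma = 20, 1000, 5.0
        x = np.linspace(1, 100, n_qc)
        design = np.column_stack([np.ones_like(x), x])
        xtx_inv = np.linalg.inv(design.T @ design)
        ok = 0
        for _ in range(n_feat):
            slope = rng.uniform(-3, 3)
            y = 1000 + slope * x + rng.normal(0, sigma, n_qc)
            m = dc.fit_linear_sequence(y, x)
            se = sigma * np.sqrt(xtx_inv[1, 1])
            ok += abs(m.slope - slope) <= 3 * se
        assert ok / n_feat >= 0.99


class TestApplyDrift:
    def _sheet(self, n):
        return dc.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"q{i}" for i in range(n)],
                    "role": "qc_train",
                    "injection_order": np.arange(1, n + 1),
                    "batch_id": "B1",
                    "tissue": "plasma",
                    "replicate_group": "qc",
                    "dilution_factor": 1.0,
                }
            )
        )

    def test_perfect_linear_drift_removed(self):
        sheet = self._sheet(11)
        vals = 100 + 10.0 * np.arange(11)
        t = pd.DataFrame({"f": vals}, index=pd.Index(sheet.sample_ids, name="sample_id"))
        models = dc.fit_linear_sequence_all(t, sheet)
        out = dc.apply_drift(t, models, sheet)
        assert rsd(out["f"]) == pytest.approx(0.0, abs=1e-9)

    def test_zero_slope_model_is_identity(self):
        sheet = self._sheet(5)
        t = pd.DataFrame({"f": [7.0] * 5}, index=pd.Index(sheet.sample_ids, name="sample_id"))
        out = dc.apply_drift(t, dc.fit_linear_sequence_all(t, sheet), sheet)
        assert np.allclose(out["f"], 7.0)

    def test_failed_fit_passes_through(self):
        sheet = self._sheet(5)
        t = pd.DataFrame({"f": [1.0, 2, 3, 4, 5]}, index=pd.Index(sheet.sample_ids, name="sample_id"))
        models = {"f": dc.DriftModel(0.0, 0.0, 0.0, 1, fit_ok=False)}
        out = dc.apply_drift(t, models, sheet)
        assert np.allclose(out["f"], t["f"])

    def test_simulated_drift_mostly_corrected(self):
        """>= 95% of drifted features reach QC_train RSD < 15% after correction."""
        table, sheet, _ = single_batch_table()
        corrected = dc.linear_sequence_correct(table, sheet)
        rsds = dc.qc_rsds(corrected, sheet, "qc_train").drop("IS_1")
        assert (rsds < 15.0).mean() >= 0.95


class TestBatchAnchor:
    def test_pure_offset_removed_exactly(self):
        spec = DriftSpec(kind="none", slope_range=0.0, batch_offsets=(1.0, 2.0), noise_cv=0.0, seed=5)
        table, sheet, _ = make_drift_table(30, 40, spec)
        corrected, bad = dc.batch_anchor_correct(table, sheet)
        assert not bad
        meta = sheet.frame.set_index("sample_id")
        qc = [s for s in sheet.ids_with_role("qc_train")]
        by_batch = corrected.loc[qc].groupby(meta.loc[qc, "batch_id"]).mean()
        ratio = by_batch.iloc[0] / by_batch.iloc[1]
        assert np.allclose(ratio, 1.0, atol=1e-12)

    def test_simulated_two_batch_qc_means_equalized(self):
        spec = DriftSpec(slope_range=0.3, batch_offsets=(1.0, 2.0), noise_cv=0.05, seed=7)
        table, sheet, _ = make_drift_table(100, 80, spec)
        corrected, _ = dc.batch_anchor_correct(table, sheet)
        meta = sheet.frame.set_index("sample_id")
        qc = [s for s in sheet.ids_with_role("qc_train")]
        by_batch = corrected.loc[qc].groupby(meta.loc[qc, "batch_id"]).mean()
        assert np.allclose(by_batch.iloc[0] / by_batch.iloc[1], 1.0, atol=1e-9)

    def test_single_batch_equals_linear_sequence(self):
        table, sheet, _ = single_batch_table(n_features=40, n_samples=30)
        via_anchor, _ = dc.batch_anchor_correct(table, sheet)
        via_linear = dc.linear_sequence_correct(table, sheet)
        # anchored to the same QC mean it was corrected to: identical tables
        assert np.allclose(via_anchor.to_numpy(), via_linear.to_numpy(), rtol=1e-12)


class TestStrategies:
    def test_none_strategy_is_identity(self):
        table, sheet, _ = single_batch_table(n_features=10, n_samples=20)
        out = dc.run_strategy(table, sheet, dc.CorrectionStrategy(("none",)))
        assert np.allclose(
            out.table.to_numpy(), dc._as_matrix(table).to_numpy(), equal_nan=True
        )

    def test_missing_is_map_is_configuration_error(self):
        table, sheet, _ = single_batch_table(n_features=5, n_samples=10)
        with pytest.raises(ConfigurationError):
            dc.run_strategy(table, sheet, dc.CorrectionStrategy(("is_norm",)))

    def test_repeated_step_rejected(self):
        with pytest.raises(ValidationError):
            dc.CorrectionStrategy(("is_norm", "is_norm"))

    def test_strategy_rerun_is_deterministic(self):
        table, sheet, _ = single_batch_table(n_features=20, n_samples=20)
        strat = dc.CorrectionStrategy(("linear_sequence",))
        a = dc.run_strategy(table, sheet, strat).table
        b = dc.run_strategy(table, sheet, strat).table
        assert a.equals(b)

    def test_default_set_has_seven_unique_strategies(self):
        strategies = dc.default_strategies()
        assert len(strategies) == 7
        assert len({s.label for s in strategies}) == 7


class TestBenchmark:
    def test_constant_features_all_pass_under_every_strategy(self):
        spec = DriftSpec(kind="none", slope_range=0.0, batch_offsets=(1.0,), noise_cv=0.0, seed=2)
        table, sheet, _ = make_drift_table(10, 20, spec, include_is=True)
        bench = dc.benchmark_strategies(
            table, sheet, is_map={f: "IS_1" for f in table.feature_ids if f != "IS_1"}
        )
        assert (bench.summary["n_lt_15"] == bench.summary["n_total"]).all()

    def test_linear_correction_never_loses_to_none_on_drifted_data(self):
        table, sheet, _ = single_batch_table(n_features=100, n_samples=60)
        strategies = [
            dc.CorrectionStrategy(("none",)),
            dc.CorrectionStrategy(("linear_sequence",)),
        ]
        bench = dc.benchmark_strategies(table, sheet, strategies)
        s = bench.summary.set_index(["strategy", "qc_set"])
        assert (
            s.loc[("linear_sequence", "qc_train"), "n_lt_30"]
            >= s.loc[("none", "qc_train"), "n_lt_30"]
        )

    def test_threshold_counts_are_nested(self):
        table, sheet, _ = single_batch_table(n_features=50, n_samples=40)
        bench = dc.benchmark_strategies(
            table, sheet, is_map={f: "IS_1" for f in table.feature_ids if f != "IS_1"}
        )
        assert (bench.summary["n_lt_15"] <= bench.summary["n_lt_30"]).all()
        assert (bench.summary["n_lt_30"] <= bench.summary["n_total"]).all()

    def test_benchmark_requires_both_qc_sets(self):
        table, sheet, _ = single_batch_table(n_features=5, n_samples=10)
        no_test = dc.SampleSheet(sheet.frame[sheet.frame["role"] != "qc_test"])
        with pytest.raises(ConfigurationError):
            dc.benchmark_strategies(table, no_test, [dc.CorrectionStrategy(("none",))])


class TestInvariants:
    def test_scale_equivariance(self):
        """Scaling the raw table by c scales corrections by c, RSDs unchanged."""
        table, sheet, _ = single_batch_table(n_features=30, n_samples=30)
        mat = dc._as_matrix(table)
        for steps in [("linear_sequence",), ("batch_anchor",)]:
            strat = dc.CorrectionStrategy(steps)
            base = dc.run_strategy(mat, sheet, strat).table
            scaled = dc.run_strategy(mat * 7.5, sheet, strat).table
            assert np.allclose(scaled.to_numpy(), 7.5 * base.to_numpy(), rtol=1e-12)

    def test_no_harm_on_driftless_data_with_many_qcs(self, rng):
        """On i.i.d. noise, linear correction barely changes QC RSD at n=50."""
        n_qc = 50
        sheet = dc.SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"q{i}" for i in range(n_qc)],
                    "role": "qc_train",
                    "injection_order": np.arange(1, n_qc + 1),
                    "batch_id": "B1",
                    "tissue": "plasma",
                    "replicate_group": "qc",
                    "dilution_factor": 1.0,
                }
            )
        )
        idx = pd.Index(sheet.sample_ids, name="sample_id")
        t = pd.DataFrame(
            {f"f{j}": 1000 * (1 + rng.normal(0, 0.05, n_qc)) for j in range(50)},
            index=idx,
        )
        before = dc.qc_rsds(t, sheet, "qc_train")
        after = dc.qc_rsds(dc.linear_sequence_correct(t, sheet), sheet, "qc_train")
        # fitting 2 parameters to 50 points absorbs ~2/n of the variance
        assert float((after - before).abs().max()) < 0.5  # percentage points
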