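import numpy as np
import pandas as pd
import pytest

from striplight import heterogeneity as het, trial_values as tv
from striplight.geometry import build_treatment, row_positions


class TestPercentDiffTruncated:
    def test_whole_period_par_contrast(self):
        west = np.mean(tv.ACC_PAR_WHOLE_PERIOD["west"])
        east = np.mean(tv.ACC_PAR_WHOLE_PERIOD["east"])
        assert het.percent_diff_truncated(west, east) == 6.5

    def test_r5_rue_contrast(self):
        west = np.mean(tv.RUE_R5["west"])
        east = np.mean(tv.RUE_R5["east"])
        assert het.percent_diff_truncated(west, east) == 5.4

    def test_equal_means(self):
        assert het.percent_diff_truncated(3.2, 3.2) == 0.0

    def test_truncates_toward_zero(self):
        assert het.percent_diff_truncated(106.59, 100.0) == 6.5
        assert het.percent_diff_truncated(93.41, 100.0) == -6.5

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            het.percent_diff_truncated(1.0, 0.0)


class TestAggregateRows:
    def test_three_row_strip(self):
        layout = row_positions(build_treatment("M2S3"))
        rec = pd.DataFrame({"row_index": [1, 2, 3], "value": [10.7, 14.6, 10.6]})
        agg = het.aggregate_rows(rec, layout).set_index("role")["value"]
        assert agg["east"] == 10.7 and agg["middle"] == 14.6 and agg["west"] == 10.6

    def test_equal_rows_give_equal_roles(self):
        layout = row_positions(build_treatment("M2S5"))
        rec = pd.DataFrame({"row_index": range(1, 6), "value": [4.0] * 5})
        agg = het.aggregate_rows(rec, layout)
        assert (agg["value"] == 4.0).all()

    def test_wide_strip_middle_is_mean_of_interior(self):
        layout = row_positions(build_treatment("M2S8"))
        rec = pd.DataFrame({"row_index": range(1, 9), "value": np.arange(1.0, 9.0)})
        agg = het.aggregate_rows(rec, layout).set_index("role")["value"]
        assert agg["middle"] == pytest.approx(np.mean(np.arange(2.0, 8.0)))
        # both whole-treatment conventions present and labelled
        assert agg["overall_row"] == pytest.approx(4.5)
        assert agg["overall_role"] == pytest.approx(np.mean([1.0, 4.5, 8.0]))

    def test_replicates_averaged_before_aggregation(self):
        layout = row_positions(build_treatment("M2S3"))
        rec = pd.DataFrame({"row_index": [1, 1, 2, 2, 3, 3],
                            "value": [9.0, 11.0, 14.0, 15.0, 10.0, 11.0]})
        agg = het.aggregate_rows(rec, layout).set_index("role")["value"]
        assert agg["east"] == 10.0 and agg["middle"] == 14.5

    def test_unknown_row_rejected(self):
        layout = row_positions(build_treatment("M2S3"))
        rec = pd.DataFrame({"row_index": [1, 2, 9], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="9"):
            het.aggregate_rows(rec, layout)


class TestDuncanMRT:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 4)
        out = het.duncan_mrt({"a": base, "b": base + 1e-9, "c": base - 1e-9})
        assert set(out.letters) == {"a"}

    def test_far_groups_distinct(self):
        rng = np.random.default_rng(1)
        out = het.duncan_mrt({
            "lo": rng.normal(0, 1, 5),
            "hi": rng.normal(100, 1, 5),
        })
        assert out.letters == ("a", "b")
        assert out.groups == ("hi", "lo")  # ordered by descending mean

    def test_letters_never_skip(self):
        # groups lying between two groups that share a letter also share it
        rng = np.random.default_rng(2)
        for trial in range(25):
            k = int(rng.integers(3, 7))
            samples = {f"g{i}": rng.normal(rng.uniform(0, 6), 1.0, 4) for i in range(k)}
            out = het.duncan_mrt(samples)
            for letter in set("".join(out.letters)):
                idx = [i for i, ls in enumerate(out.letters) if letter in ls]
                assert idx == list(range(min(idx), max(idx) + 1))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        samples = {f"g{i}": rng.normal(i, 1.0, 4) for i in range(4)}
        out1 = het.duncan_mrt(samples)
        renamed = {f"x{k}": v for k, v in reversed(list(samples.items()))}
        out2 = het.duncan_mrt(renamed)
        assert out1.letters == out2.letters
        assert [m for m in out1.means] == pytest.approx([m for m in out2.means])

    def test_critical_ranges_match_published_tables(self):
        # Duncan's 5% significant studentized ranges at 20 error df
        ranges = het._duncan_ranges(4, 20, 0.05)
        assert ranges[0] == pytest.approx(2.950, abs=2e-3)   # p = 2
        assert ranges[1] == pytest.approx(3.097, abs=2e-3)   # p = 3
        assert ranges[2] == pytest.approx(3.190, abs=2e-3)   # p = 4

    def test_requires_replicates(self):
        with pytest.raises(ValueError, match="replicate"):
            het.duncan_mrt({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestLinearFit:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = het.linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        fit = het.linear_fit(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 30, 40)
        y = 0.7 * x + rng.normal(0, 2, 40)
        fit = het.linear_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)
        assert fit.r2 == pytest.approx(r2, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            het.linear_fit(np.ones(5), np.arange(5.0))
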