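"""Preprocessing primitives against hand-computed and independent oracles."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from ajlung.preprocess import (
    DetectionCalls,
    detect_outlier_arrays,
    detection_calls,
    filter_present,
    median_polish,
    median_polish_summarize,
    median_summarize,
    normexp_correct,
    normexp_signal,
    probe_map_from_ids,
    quantile_normalize,
    rle_report,
)


class TestNormexp:
    def test_constant_array_maps_to_offset(self):
        raw = pd.DataFrame({"a": [5.0] * 10, "b": [5.0] * 10})
        out = normexp_correct(raw, offset=10.0)
        assert (out >= 10.0).all().all()
        assert out["a"].nunique() == 1

    def test_identical_arrays_give_identical_outputs(self, rng):
        x = rng.exponential(50, 200) + rng.normal(100, 5, 200)
        raw = pd.DataFrame({"a": x, "b": x})
        out = normexp_correct(raw)
        np.testing.assert_array_equal(out["a"], out["b"])

    def test_monotone_and_strictly_positive(self, rng):
        x = np.sort(rng.exponential(80, 500) + rng.normal(60, 10, 500))
        out = normexp_correct(pd.DataFrame({"a": x}), offset=0.0)
        v = out["a"].to_numpy()
        assert (np.diff(v) >= -1e-9).all()
        assert (v > 0).all()

    def test_signal_formula_matches_numerical_integration(self):
        """E[S | X=x] under normal background + exponential signal, closed
        form vs direct numerical integration of the conditional density."""
        mu, sigma, alpha = 30.0, 8.0, 120.0
        for x in (20.0, 55.0, 150.0, 600.0):
            def integrand_num(s):
                return s * stats.expon.pdf(s, scale=alpha) * stats.norm.pdf(x - s, mu, sigma)

            def integrand_den(s):
                return stats.expon.pdf(s, scale=alpha) * stats.norm.pdf(x - s, mu, sigma)

            hi = x + 10 * sigma  # density support: s near x - mu, width ~sigma
            pts = [max(0.0, x - mu - 10 * sigma), max(0.0, x - mu)]
            num, _ = integrate.quad(integrand_num, 0, hi, points=pts, limit=300)
            den, _ = integrate.quad(integrand_den, 0, hi, points=pts, limit=300)
            closed = normexp_signal(mu, sigma, alpha, np.array([x]))[0]
            assert closed == pytest.approx(num / den, rel=1e-6)

    def test_large_signal_asymptote(self):
        """Far above background the corrected value approaches x - mu - s^2/a."""
        mu, sigma, alpha = 30.0, 5.0, 100.0
        x = 5000.0
        out = normexp_signal(mu, sigma, alpha, np.array([x]))[0]
        assert out == pytest.approx(x - mu - sigma**2 / alpha, rel=1e-6)

    def test_nonfinite_input_names_array(self):
        raw = pd.DataFrame({"bad_array": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match="bad_array"):
            normexp_correct(raw)


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_sorted_columns_identical_and_ranks_preserved(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        out = quantile_normalize(m)
        ref = np.sort(out.to_numpy()[:, 0])
        for j in range(6):
            np.testing.assert_allclose(np.sort(out.to_numpy()[:, j]), ref)
            assert (
                stats.rankdata(out.to_numpy()[:, j]) == stats.rankdata(m.to_numpy()[:, j])
            ).all()

    def test_idempotent_on_equal_distributions(self, rng):
        col = rng.normal(size=30)
        m = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m, check_exact=False, atol=1e-12)

    def test_single_column_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)


def _naive_median_polish(block, n_iter=2000):
    """Deliberately plain re-implementation: sweep to convergence with
    explicit loops; independent of the package's vectorized version."""
    r = [row[:] for row in block]
    nr, nc = len(r), len(r[0])
    overall, row_eff, col_eff = 0.0, [0.0] * nr, [0.0] * nc
    for _ in range(n_iter):
        for i in range(nr):
            med = float(np.median(r[i]))
            row_eff[i] += med
            for j in range(nc):
                r[i][j] -= med
        med = float(np.median(row_eff))
        overall += med
        row_eff = [v - med for v in row_eff]
        for j in range(nc):
            med = float(np.median([r[i][j] for i in range(nr)]))
            col_eff[j] += med
            for i in range(nr):
                r[i][j] -= med
        med = float(np.median(col_eff))
        overall += med
        col_eff = [v - med for v in col_eff]
    return overall, row_eff, col_eff


class TestMedianPolish:
    def test_additive_block_recovered_exactly(self):
        a = np.array([1.0, 2.0, 5.0])
        b = np.array([0.0, 3.0, 4.0, 10.0])
        block = a[:, None] + b[None, :]
        overall, row, col, resid = median_polish(block)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)
        np.testing.assert_allclose(overall + col, b + np.median(a), atol=1e-12)

    def test_single_probe_feature_passthrough(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f1|p1"], columns=list("abc"))
        out = median_polish_summarize(m, probe_map_from_ids(m.index))
        np.testing.assert_allclose(out.loc["f1"], [1.0, 2.0, 3.0])

    def test_random_blocks_match_naive_oracle(self, rng):
        for _ in range(5):
            block = rng.normal(size=(5, 6))
            overall, _, col, _ = median_polish(block, max_iter=500, tol=1e-14)
            o2, _, c2 = _naive_median_polish(block.tolist())
            np.testing.assert_allclose(overall + col, np.array(c2) + o2, atol=1e-8)

    def test_outlier_cell_block_matches_oracle(self, rng):
        block = np.add.outer(rng.normal(size=3), rng.normal(size=3))
        block[1, 2] += 10.0
        overall, _, col, _ = median_polish(block, max_iter=500, tol=1e-14)
        o2, _, c2 = _naive_median_polish(block.tolist())
        np.testing.assert_allclose(overall + col, np.array(c2) + o2, atol=1e-8)

    def test_matches_r_medpolish(self, rng, tmp_path):
        """Cross-check the summary against R's stats::medpolish."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript expected on PATH in this environment")
        block = rng.normal(size=(4, 5)).round(6)
        csv = tmp_path / "block.csv"
        np.savetxt(csv, block, delimiter=",")
        script = (
            f'x <- as.matrix(read.csv("{csv}", header=FALSE));'
            "fit <- medpolish(x, eps=1e-12, maxiter=200, trace.iter=FALSE);"
            'cat(fit$overall + fit$col, sep=",")'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in res.stdout.strip().split(",")])
        overall, _, col, _ = median_polish(block, max_iter=500, tol=1e-14)
        np.testing.assert_allclose(overall + col, expected, atol=1e-6)


class TestMedianSummarize:
    @pytest.mark.parametrize(
        "values,expected", [([3.0, 5.0, 9.0], 5.0), ([3.0, 5.0], 4.0)]
    )
    def test_median_over_probes(self, values, expected):
        m = pd.DataFrame(
            {"s1": values}, index=[f"f|p{i}" for i in range(1, len(values) + 1)]
        )
        out = median_summarize(m, probe_map_from_ids(m.index))
        assert out.loc["f", "s1"] == expected

    def test_probe_order_invariance(self, rng):
        vals = rng.normal(size=(6, 3))
        idx = [f"f{i % 2}|p{i}" for i in range(6)]
        m = pd.DataFrame(vals, index=idx, columns=list("abc"))
        shuffled = m.iloc[rng.permutation(6)]
        out1 = median_summarize(m, probe_map_from_ids(m.index))
        out2 = median_summarize(shuffled, probe_map_from_ids(shuffled.index))
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())


class TestDetectionCalls:
    def test_hundred_distinct_values_five_absent(self, rng):
        raw = pd.DataFrame({"a": rng.permutation(np.arange(100.0) + 1)})
        calls = detection_calls(raw, percentile=0.05)
        assert (~calls.calls["a"]).sum() == 5

    def test_all_equal_array_all_absent(self):
        raw = pd.DataFrame({"a": [7.0] * 20})
        calls = detection_calls(raw)
        assert (~calls.calls["a"]).all()  # ties at threshold are absent

    def test_percentile_one_makes_all_absent(self, rng):
        raw = pd.DataFrame({"a": rng.uniform(1, 100, 50)})
        calls = detection_calls(raw, percentile=1.0)
        assert (~calls.calls["a"]).all()

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            detection_calls(pd.DataFrame({"a": [1.0]}), percentile=0.0)


class TestFilterPresent:
    @staticmethod
    def _sheet():
        rows = []
        for dose in ("sham", "L", "M", "H"):
            for i in range(10):
                rows.append(
                    {
                        "sample_id": f"{dose}_{i}",
                        "tissue": "P" if i < 5 else "T",
                        "dose": dose,
                        "animal_id": f"a{i}",
                        "is_replicate": False,
                    }
                )
        return pd.DataFrame(rows)

    def _calls(self, present_per_group):
        sheet = self._sheet()
        cols = list(sheet["sample_id"])
        calls = pd.DataFrame(False, index=["f"], columns=cols)
        for dose, k in present_per_group.items():
            ids = [c for c in cols if c.startswith(f"{dose}_")][:k]
            calls.loc["f", ids] = True
        return DetectionCalls(calls=calls, thresholds=pd.Series(0.0, index=cols), percentile=0.05), sheet

    def test_present_in_half_of_one_group_kept(self):
        calls, sheet = self._calls({"sham": 5})
        assert filter_present(calls, sheet) == ["f"]

    def test_absent_everywhere_dropped(self):
        calls, sheet = self._calls({})
        assert filter_present(calls, sheet) == []

    def test_present_under_half_everywhere_dropped(self):
        calls, sheet = self._calls({"sham": 4, "L": 4, "M": 4, "H": 4})
        assert filter_present(calls, sheet) == []

    def test_unknown_sample_errors(self):
        calls, sheet = self._calls({"sham": 5})
        with pytest.raises(ValueError, match="missing"):
            filter_present(calls, sheet[sheet["dose"] != "sham"])


class TestOutlierArrays:
    def test_permuted_array_flagged_and_order_invariant(self, rng):
        base = rng.normal(8, 1, 400)
        cols = {f"a{i}": base + rng.normal(0, 0.1, 400) for i in range(6)}
        cols["perm"] = rng.permutation(base)
        m = pd.DataFrame(cols)
        qc = detect_outlier_arrays(m)
        assert qc.excluded == ["perm"]
        qc2 = detect_outlier_arrays(m[list(reversed(m.columns))])
        assert set(qc2.excluded) == {"perm"}

    def test_identical_arrays_none_flagged(self):
        m = pd.DataFrame({c: np.arange(50.0) for c in "abcd"})
        assert detect_outlier_arrays(m).excluded == []

    def test_too_few_arrays_warns(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        qc = detect_outlier_arrays(m)
        assert qc.excluded == [] and qc.warnings


class TestRle:
    def test_identical_arrays_zero_medians(self):
        m = pd.DataFrame({c: np.arange(30.0) for c in "abc"})
        qc = rle_report(m)
        np.testing.assert_allclose(qc.rle_median, 0.0, atol=1e-12)

    def test_shifted_array_shows_its_shift(self, rng):
        base = rng.normal(8, 1, 500)
        m = pd.DataFrame({"a": base, "b": base, "c": base, "d": base + 1.0})
        qc = rle_report(m)
        assert qc.rle_median["d"] == pytest.approx(1.0, abs=0.05)
        assert abs(qc.rle_median["a"]) < 0.05
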