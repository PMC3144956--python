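"""Array normalization, detection, differential expression and 2^-ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmeta.expression import (call_detection, cluster_and_scale,
                                ddct_quantify, dendrogram_newick,
                                differential_expression,
                                normalize_cyclic_lowess, subtract_background)
from mirmeta.simulate import SimConfig, simulate_array, simulate_ct


def stage_frame(values_17, values_29, probes=None):
    n = len(values_17)
    probes = probes or [f"p{i}" for i in range(n)]
    cols = {}
    for r in range(3):
        cols[f"17dph_r{r + 1}"] = [v[r] for v in values_17]
        cols[f"29dph_r{r + 1}"] = [v[r] for v in values_29]
    return pd.DataFrame(cols, index=probes)


class TestBackground:
    def test_scalar_subtraction_and_floor(self):
        df = pd.DataFrame({"a": [100.0, 30.0, 0.0]})
        out = subtract_background(df, 40.0)
        assert list(out["a"]) == [60.0, 0.0, 0.0]

    def test_zero_background_is_identity(self):
        df = pd.DataFrame({"a": [10.0, 20.0]})
        assert subtract_background(df, 0.0).equals(df)

    def test_per_probe_background(self):
        df = pd.DataFrame({"a": [100.0, 100.0]}, index=["x", "y"])
        out = subtract_background(df, pd.Series([10.0, 90.0], index=["x", "y"]))
        assert list(out["a"]) == [90.0, 10.0]

    def test_missing_background_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(pd.DataFrame({"a": [1.0]}), None)


class TestCyclicLowess:
    def test_identical_arrays_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 1000, 200)
        df = pd.DataFrame({"a": x, "b": x})
        out = normalize_cyclic_lowess(df)
        assert np.allclose(out["a"], df["a"], rtol=1e-6)

    def test_constant_factor_removed(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 1000, 500)
        df = pd.DataFrame({"a": x, "b": 2.0 * x})
        out = normalize_cyclic_lowess(df)
        m = np.log2(out["a"] + 1) - np.log2(out["b"] + 1)
        assert abs(np.median(m)) < 0.05

    def test_intensity_dependent_bias_removed(self):
        """Planted M = 0.5*sin(A) bias shrinks below |median| 0.05."""
        rng = np.random.default_rng(2)
        log_a = rng.uniform(4, 10, 800)
        a_lin = 2.0 ** log_a
        bias = 0.5 * np.sin(log_a)
        b_lin = 2.0 ** (log_a + bias)
        df = pd.DataFrame({"a": a_lin, "b": b_lin})
        out = normalize_cyclic_lowess(df)
        m = np.log2(out["a"] + 1) - np.log2(out["b"] + 1)
        assert abs(np.median(m)) < 0.05
        # and locally, in thirds of the intensity range
        order = np.argsort(log_a)
        for chunk in np.array_split(m.to_numpy()[order], 3):
            assert abs(np.median(chunk)) < 0.05

    def test_single_array_rejected(self):
        with pytest.raises(ValueError):
            normalize_cyclic_lowess(pd.DataFrame({"a": [1.0, 2.0]}))

    def test_probe_order_preserved(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.uniform(1, 100, 50),
                           "b": rng.uniform(1, 100, 50)},
                          index=[f"probe{i}" for i in range(50)])
        out = normalize_cyclic_lowess(df)
        assert list(out.index) == list(df.index)
        assert list(out.columns) == list(df.columns)


class TestDetection:
    @pytest.mark.parametrize("mean,expected", [
        (31.0, False), (32.0, False), (33.0, True), (0.0, False)])
    def test_threshold_boundary(self, mean, expected):
        df = stage_frame([(mean,) * 3], [(mean,) * 3])
        flags = call_detection(df)
        assert flags.loc["p0", "17dph"] == expected
        assert flags.loc["p0", "29dph"] == expected


class TestDifferentialExpression:
    def test_identical_replicates_not_significant(self):
        df = stage_frame([(100.0,) * 3], [(100.0,) * 3])
        out = differential_expression(df)
        assert out["p_value"].item() == 1.0
        assert not out["significant"].item()

    def test_planted_eightfold_change_detected_with_direction(self):
        cfg = SimConfig(seed=8, array_n_mirnas=60, array_n_de=6,
                        array_effect_log2=3.0, replicate_cv=0.05)
        signals, truth = simulate_array(cfg)
        out = differential_expression(signals)
        for probe in truth[truth["is_de"]].index:
            assert out.loc[probe, "significant"]
            expected_dir = ("up_29dph" if truth.loc[probe, "true_log2_effect"] > 0
                            else "up_17dph")
            assert out.loc[probe, "direction"] == expected_dir

    def test_tier_split_at_500(self):
        df = stage_frame([(700.0, 701.0, 699.0), (300.0, 301.0, 299.0)],
                         [(300.0, 301.0, 299.0), (100.0, 101.0, 99.0)])
        out = differential_expression(df)
        assert out["tier"].tolist() == ["high", "low"]

    def test_undetected_probe_untested(self):
        df = stage_frame([(5.0, 6.0, 7.0)], [(4.0, 6.0, 8.0)])
        out = differential_expression(df)
        assert not out["detected"].item()
        assert np.isnan(out["p_value"].item())

    def test_fdr_flag_adds_adjusted_column(self):
        df = stage_frame([(100.0, 101.0, 99.0)] * 4,
                         [(200.0, 201.0, 199.0)] * 4)
        out = differential_expression(df, fdr=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"] >= out["p_value"]).all()

    def test_type_i_error_calibrated_on_null_arrays(self):
        """Null fraction with p<0.01 within 99.9% binomial bounds."""
        from scipy import stats

        cfg = SimConfig(seed=42, array_n_mirnas=2000, array_n_de=0,
                        replicate_cv=0.1, array_low_fraction=0.0)
        signals, _ = simulate_array(cfg)
        out = differential_expression(signals)
        k = int(out["significant"].sum())
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 2000, 0.01)
        assert lo <= k <= hi

    def test_power_at_planted_log2_effect_three(self):
        """>= 90% of 8-fold effects recovered at cv 0.1, n=3."""
        hits = total = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, array_n_mirnas=100, array_n_de=10,
                            array_effect_log2=3.0, replicate_cv=0.1)
            signals, truth = simulate_array(cfg)
            out = differential_expression(signals)
            hits += int(out.loc[truth[truth["is_de"]].index, "significant"].sum())
            total += 10
        assert hits / total >= 0.9


class TestClustering:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[9.0, 1.0, 5.0]],
                          index=["a", "b", "c"])
        _, names, root = cluster_and_scale(df)
        first = min((root.left, root.right), key=lambda n: n.dist)
        assert first.dist == pytest.approx(0.0)

    def test_scaled_values_clipped(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 1000, size=(20, 6)))
        scaled, _, _ = cluster_and_scale(df)
        assert scaled.to_numpy().max() <= 1.5
        assert scaled.to_numpy().min() >= -1.5

    def test_constant_row_scales_to_zero(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                          index=["flat", "var"])
        scaled, _, _ = cluster_and_scale(df)
        assert (scaled.loc["flat"] == 0.0).all()

    def test_anticorrelated_clusters_split_at_root(self):
        up = [[1.0, 2.0, 10.0, 11.0]] * 3
        down = [[11.0, 10.0, 2.0, 1.0]] * 3
        df = pd.DataFrame(up + down,
                          index=[f"u{i}" for i in range(3)]
                                + [f"d{i}" for i in range(3)])
        _, names, root = cluster_and_scale(df)
        left = {names[i] for i in range(3)}
        assert left in ({"u0", "u1", "u2"}, {"d0", "d1", "d2"})

    def test_newick_serialization(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.1], [5.0, 1.0]],
                          index=["a", "b", "c"])
        _, names, root = cluster_and_scale(df)
        text = dendrogram_newick(root, list(df.sort_index().index))
        assert text.endswith(";") and set("abc") <= set(text)


class TestDdct:
    def ct_frame(self, target_17, target_29, ref=(15.0,) * 3):
        rows = []
        for stage, vals in (("17dph", target_17), ("29dph", target_29)):
            for i, v in enumerate(vals):
                rows.append({"gene": "mir-x", "stage": stage,
                             "replicate": i + 1, "ct": v})
            for i, v in enumerate(ref):
                rows.append({"gene": "5S_rRNA", "stage": stage,
                             "replicate": i + 1, "ct": v})
        return pd.DataFrame(rows)

    def test_equal_dct_gives_fold_one(self):
        ct = self.ct_frame((20.0,) * 3, (20.0,) * 3)
        out = ddct_quantify(ct, target="mir-x")
        assert out["fold_change"] == pytest.approx(1.0)
        assert not out["significant"]

    def test_ddct_minus_two_gives_fold_four(self):
        ct = self.ct_frame((22.0,) * 3, (20.0,) * 3)
        out = ddct_quantify(ct, target="mir-x")
        assert out["ddct"] == pytest.approx(-2.0)
        assert out["fold_change"] == pytest.approx(4.0)

    @given(st.floats(min_value=-8, max_value=8))
    @settings(max_examples=30, deadline=None)
    def test_constant_ct_shift_invariance(self, shift):
        base = self.ct_frame((22.0, 22.1, 21.9), (20.0, 20.2, 19.8))
        shifted = base.assign(ct=base["ct"] + shift)
        a = ddct_quantify(base, target="mir-x")
        b = ddct_quantify(shifted, target="mir-x")
        assert b["fold_change"] == pytest.approx(a["fold_change"])
        assert b["p_value"] == pytest.approx(a["p_value"])

    def test_missing_reference_rejected(self):
        ct = self.ct_frame((20.0,) * 3, (20.0,) * 3)
        ct = ct[ct["gene"] != "5S_rRNA"]
        with pytest.raises(ValueError):
            ddct_quantify(ct, target="mir-x")

    def test_recovered_fold_near_planted_under_noise(self):
        """sigma=0.1 cycles, planted 4-fold: estimate within [3.5, 4.6]."""
        cfg = SimConfig(seed=21, ct_noise_sd=0.1)
        ct, _ = simulate_ct(cfg, fold_changes={"mir-x": 4.0})
        out = ddct_quantify(ct, target="mir-x")
        assert 3.5 <= out["fold_change"] <= 4.6
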