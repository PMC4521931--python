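"""z-score standardization, confidence tiers, fold change, and ddCt."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from silacq import fixtures, ratio_stats as rs

ML_PARAMS = rs.NormalizationParams(-0.072, 1.237, "M/L")


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "r,expected", [(39.51, 5.30), (1.0, 0.0), (0.25, -2.0)]
    )
    def test_examples(self, r, expected):
        assert rs.log2_ratio(r) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("r", [0.0, -1.0, float("inf")])
    def test_domain_errors(self, r):
        with pytest.raises(ValueError):
            rs.log2_ratio(r)


class TestFitParams:
    def test_mean_and_sample_sd(self):
        p = rs.fit_params([-1.0, 0.0, 1.0])
        assert p.mean_log2 == 0.0
        assert p.sd_log2 == pytest.approx(1.0)  # n-1 denominator

    def test_constant_population_flagged(self):
        with pytest.raises(rs.DegeneratePopulationError):
            rs.fit_params([0.5] * 10)

    def test_too_few_values(self):
        with pytest.raises(rs.InsufficientDataError):
            rs.fit_params([1.0])

    def test_recovers_population_parameters(self):
        """Sampling-theory check at the study's population size."""
        rng = np.random.default_rng(123)
        true_mean, true_sd, n = -0.07, 1.2, 1766
        p = rs.fit_params(rng.normal(true_mean, true_sd, n))
        # 3 standard errors: SE(mean)=sd/sqrt(n), SE(sd)~sd/sqrt(2n)
        assert abs(p.mean_log2 - true_mean) < 3 * true_sd / math.sqrt(n)
        assert abs(p.sd_log2 - true_sd) < 3 * true_sd / math.sqrt(2 * n)


class TestZScore:
    @pytest.mark.parametrize(
        "log2_value,expected",
        [
            (math.log2(39.51), 4.35),   # thymidine phosphorylase, M/L
            (-2.53, -1.99),             # HLA-C, M/L
            (3.24, 2.68),               # UCHL1, H/L under shared params
            (-0.072, 0.0),
        ],
    )
    def test_worked_values(self, log2_value, expected):
        assert rs.zscore(log2_value, ML_PARAMS) == pytest.approx(expected, abs=0.02)

    def test_self_standardization_is_exact(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.3, 2.0, 5000)
        p = rs.fit_params(vals)
        z = (vals - p.mean_log2) / p.sd_log2
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12


class TestConfidenceThresholds:
    @pytest.mark.parametrize(
        "level,sigma", [(95, 1.960), (99, 2.576), (99.9, 3.291)]
    )
    def test_two_sided_critical_values(self, level, sigma):
        assert rs.confidence_to_threshold(level) == pytest.approx(sigma, abs=5e-4)

    @pytest.mark.parametrize("level", [0, 100, -5, 120])
    def test_domain(self, level):
        with pytest.raises(ValueError):
            rs.confidence_to_threshold(level)


class TestAverageZ:
    @pytest.mark.parametrize(
        "zs,expected", [([2.0, 3.0], 2.5), ([1.7], 1.7), ([-2.0, 2.0], 0.0)]
    )
    def test_examples(self, zs, expected):
        assert rs.average_z(zs) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rs.average_z([])


class TestClassify:
    @pytest.mark.parametrize(
        "z,tier,direction",
        [
            (2.00, 95.0, "up"),
            (-3.50, 99.9, "down"),
            (1.95, 0.0, "none"),
            (1.96, 95.0, "up"),      # inclusive at the printed threshold
            (2.576, 99.0, "up"),
            (float("nan"), 0.0, "none"),
        ],
    )
    def test_tiers(self, z, tier, direction):
        assert rs.classify(z) == (tier, direction)

    @given(z=st.floats(-6, 6), dz=st.floats(0, 3))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_magnitude(self, z, dz):
        bigger = z + dz if z >= 0 else z - dz
        assert rs.classify(bigger)[0] >= rs.classify(z)[0]


class TestFoldChange:
    @pytest.mark.parametrize(
        "r,expected", [(39.51, 39.51), (0.17, 5.88), (1.0, 1.0)]
    )
    def test_examples(self, r, expected):
        assert rs.fold_change(r) == pytest.approx(expected, abs=5e-3)

    @given(r=st.floats(1e-6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_symmetry(self, r):
        # symmetry up to one rounding of the reciprocal
        assert rs.fold_change(r) == pytest.approx(
            rs.fold_change(1.0 / r), rel=1e-12
        )
        assert rs.fold_change(r) >= 1.0


class TestCountRegulated:
    @staticmethod
    def _classified_fixture():
        df = fixtures.load_regulated_tables()
        return rs.classify_table(df)

    def test_upregulated_table_counts(self):
        t2 = rs.classify_table(fixtures.load_table2())
        counts = rs.count_regulated(t2, 95.0)
        assert counts["ml_up"] == 36
        assert counts["hl_up"] == 17

    def test_downregulated_table_counts(self):
        t3 = rs.classify_table(fixtures.load_table3())
        counts = rs.count_regulated(t3, 95.0)
        assert counts["ml_down"] == 74
        assert counts["hl_down"] == 70

    def test_empty_records(self):
        empty = pd.DataFrame({"z_ml": [], "z_hl": []})
        counts = rs.count_regulated(rs.classify_table(empty), 95.0)
        assert counts["ml_up"] == counts["ml_down"] == 0


class TestDdct:
    @pytest.mark.parametrize(
        "ddct,expected", [(0.0, 1.0), (-1.0, 2.0), (2.0, 0.25)]
    )
    def test_fold(self, ddct, expected):
        m = rs.DdctMeasurement(20.0 + ddct, 18.0, 22.0, 20.0)
        assert rs.ddct_fold(m) == pytest.approx(expected)


class TestZScoreTable:
    def test_paper_compat_uses_shared_params(self):
        per_rep = pd.DataFrame(
            {
                "protein": ["A", "B", "C"],
                "replicate": ["r1"] * 3,
                "ml_ratio": [39.51, 1.0, 0.17],
                "hl_ratio": [9.45, 1.0, 0.02],
            }
        )
        rec, params = rs.zscore_table(
            per_rep, mode="paper-compat", shared_params=ML_PARAMS
        )
        a = rec.set_index("protein")
        assert a.loc["A", "z_ml"] == pytest.approx(4.35, abs=0.02)
        assert a.loc["A", "z_hl"] == pytest.approx(2.68, abs=0.02)

    def test_per_channel_standardizes_each_data_set(self):
        rng = np.random.default_rng(5)
        n = 400
        per_rep = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(n)] * 2,
                "replicate": ["r1"] * n + ["r2"] * n,
                "ml_ratio": 2.0 ** rng.normal(1.0, 0.5, 2 * n),
                "hl_ratio": 2.0 ** rng.normal(-1.0, 2.0, 2 * n),
            }
        )
        rec, params = rs.zscore_table(per_rep, mode="per-channel")
        assert len(params) == 4  # 2 channels x 2 replicates
        # each data set self-standardizes: averaged z near 0 mean
        assert abs(rec["z_ml"].mean()) < 0.05
        assert abs(rec["z_hl"].mean()) < 0.05
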