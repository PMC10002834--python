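"""Agreement statistics: Bland-Altman, correlation, comparison joins."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcpcflow.stats import (PairedComparison, bland_altman, comparison_table,
                            pearson_r)
from tcpcflow.synthetic import synth_mcl_measurements


def _pc(a, b):
    return PairedComparison([str(i) for i in range(len(a))], a, b)


class TestBlandAltman:
    def test_identical_series_degenerate(self):
        r = bland_altman(_pc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert r.mean_diff == 0.0
        assert r.sd_diff == 0.0
        assert r.ci95_mean_diff == (0.0, 0.0)
        assert r.loa95 == (0.0, 0.0)

    def test_hand_computed_two_pairs(self):
        # d = [-0.2, -0.4]: mean -0.3, sd 0.1414, LoA -0.3 -+ 1.96 sd
        r = bland_altman(_pc([1.0, 2.0], [1.2, 2.4]))
        assert r.mean_diff == pytest.approx(-0.3)
        assert r.sd_diff == pytest.approx(0.14142, rel=1e-4)
        assert r.loa95[0] == pytest.approx(-0.57718, rel=1e-3)
        assert r.loa95[1] == pytest.approx(-0.02282, rel=1e-2)

    def test_shift_invariance(self):
        a = np.array([1.0, 2.5, 4.0])
        b = np.array([1.1, 2.2, 4.4])
        r1 = bland_altman(_pc(a, b))
        r2 = bland_altman(_pc(a + 7.3, b + 7.3))
        assert r1.mean_diff == pytest.approx(r2.mean_diff)
        assert r1.loa95 == pytest.approx(r2.loa95)

    def test_loa_contains_mean_and_ci_narrows_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (10, 40, 160):
            a = rng.normal(5, 1, n)
            b = a + rng.normal(0.3, 0.2, n)
            r = bland_altman(_pc(a, b))
            assert r.loa95[0] <= r.mean_diff <= r.loa95[1]
            widths.append(r.ci95_mean_diff[1] - r.ci95_mean_diff[0])
        assert widths[0] > widths[1] > widths[2]

    def test_recovers_configured_bias_and_noise(self):
        """Synthetic bench pipeline: configured bias/SD re-estimated."""
        n, bias, sd = 200, 0.23, 0.15
        model = np.linspace(0.2, 2.0, n)
        ds = synth_mcl_measurements(model, bias=bias, noise_sd=sd, seed=42)
        measured = ds.table["dP_mmHg"].to_numpy()
        r = bland_altman(_pc(measured, model))
        assert abs(r.mean_diff - bias) < 3 * sd / np.sqrt(n)
        assert abs(r.sd_diff - sd) / sd < 0.15

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            _pc([1.0], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(_pc(a, 2 * a + 1)) == pytest.approx(1.0)
        assert pearson_r(_pc(a, -a)) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_r(_pc([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])) == \
            pytest.approx(0.98198, rel=1e-4)

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, shift):
        a = np.array([1.0, 2.0, 3.5, 4.1, 6.0])
        b = np.array([1.2, 1.9, 3.9, 3.8, 6.3])
        r0 = pearson_r(_pc(a, b))
        assert pearson_r(_pc(scale * a + shift, b)) == \
            pytest.approx(r0, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(_pc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestComparisonTable:
    def _cfd(self, cos, models, dp=1.0):
        rows = [{"CO_L_min": c, "model": m, "dP_max_mmHg": dp + c / 10}
                for m in models for c in cos]
        return pd.DataFrame(rows)

    def test_full_join_cardinality(self):
        cos = [3.0, 5.0, 7.0, 9.0, 11.0]
        models = ["blank", "vip109", "vip162"]
        cfd = self._cfd(cos, models)
        mcl = pd.DataFrame([{"CO_L_min": c, "model": m, "dP_mmHg": 1.0}
                            for m in models for c in cos])
        joined, unmatched = comparison_table(cfd, mcl)
        assert len(joined) == 15
        assert unmatched == []

    def test_missing_case_reported(self):
        cos = [3.0, 5.0]
        cfd = self._cfd(cos, ["blank"])
        mcl = pd.DataFrame([{"CO_L_min": 3.0, "model": "blank",
                             "dP_mmHg": 1.0}])
        joined, unmatched = comparison_table(cfd, mcl)
        assert len(joined) == 1
        assert len(unmatched) == 1

    def test_empty_inputs(self):
        cfd = pd.DataFrame(columns=["CO_L_min", "model", "dP_max_mmHg"])
        mcl = pd.DataFrame(columns=["CO_L_min", "model", "dP_mmHg"])
        joined, unmatched = comparison_table(cfd, mcl)
        assert len(joined) == 0

    def test_duplicate_keys_rejected(self):
        cfd = pd.concat([self._cfd([3.0], ["blank"])] * 2)
        mcl = pd.DataFrame([{"CO_L_min": 3.0, "model": "blank",
                             "dP_mmHg": 1.0}])
        with pytest.raises(ValueError, match="duplicate"):
            comparison_table(cfd, mcl)
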