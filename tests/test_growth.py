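"""Tumor volume, RTV, TGI, RTVV and relapse operations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pdxsig import growth
from pdxsig.config import SimulationConfig
from pdxsig.synthetic import simulate_growth_study, simulate_relapse


def make_study(rows):
    return growth.GrowthStudy(pd.DataFrame(rows, columns=["mouse", "model", "arm", "day", "a", "b"]))


def two_arm_study(control_vols, treated_vols, days):
    """Build a one-model study with prescribed per-mouse volume series."""
    rows = []
    for arm, series in (("control", control_vols), ("treated", treated_vols)):
        for i, vols in enumerate(series):
            for day, v in zip(days, vols):
                b = (2 * v) ** (1 / 3)  # a == b spheroid
                rows.append([f"{arm}{i}", "M1", arm, day, b, b])
    return make_study(rows)


class TestTumorVolume:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(10, 5, 125.0), (2, 2, 4.0), (17.1, 12.4, 1314.648)],
    )
    def test_formula(self, a, b, expected):
        assert growth.tumor_volume(a, b) == pytest.approx(expected)

    def test_rejects_swapped_diameters(self):
        with pytest.raises(growth.MeasurementOrderError):
            growth.tumor_volume(5, 10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            growth.tumor_volume(5, 0)


class TestRTV:
    def test_constant_volume_gives_unit_rtv(self):
        df = pd.DataFrame({"mouse": ["m"] * 3, "day": [0, 7, 14], "volume": [100.0] * 3})
        assert growth.relative_tumor_volume(df)["rtv"].tolist() == [1, 1, 1]

    def test_doubling_series(self):
        df = pd.DataFrame({"mouse": ["m"] * 4, "day": [0, 1, 2, 3], "volume": [50.0, 100, 200, 400]})
        assert growth.relative_tumor_volume(df)["rtv"].tolist() == [1, 2, 4, 8]

    def test_direct_division(self):
        df = pd.DataFrame({"mouse": ["m"] * 3, "day": [0, 3, 7], "volume": [100.0, 150.0, 240.0]})
        assert growth.relative_tumor_volume(df)["rtv"].tolist() == [1.0, 1.5, 2.4]

    def test_missing_baseline_rejected(self):
        df = pd.DataFrame({"mouse": ["m"] * 2, "day": [3, 7], "volume": [100.0, 150.0]})
        with pytest.raises(ValueError, match="baseline"):
            growth.relative_tumor_volume(df)

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.01, 100), v0=st.floats(10, 500), g=st.floats(1.0, 3.0))
    def test_scale_invariance(self, scale, v0, g):
        vols = [v0, v0 * g, v0 * g * g]
        df = pd.DataFrame({"mouse": ["m"] * 3, "day": [0, 1, 2], "volume": vols})
        df2 = df.assign(volume=df["volume"] * scale)
        r1 = growth.relative_tumor_volume(df)["rtv"]
        r2 = growth.relative_tumor_volume(df2)["rtv"]
        assert np.allclose(r1, r2, rtol=1e-12)


class TestTGI:
    days = [0, 7, 14]

    def test_identical_arms_zero_tgi(self):
        series = [[100, 200, 400], [120, 240, 480]]
        study = two_arm_study(series, series, self.days)
        curve, opt, _ = growth.tgi_curve(study, "M1")
        assert np.allclose(curve["tgi"], 0, atol=1e-9)
        assert opt == pytest.approx(0, abs=1e-9)

    def test_growth_arrest_case(self):
        control = [[100, 500, 1000], [100, 500, 1000]]
        treated = [[100, 100, 100], [100, 100, 100]]
        study = two_arm_study(control, treated, self.days)
        curve, opt, day = growth.tgi_curve(study, "M1")
        assert opt == pytest.approx(90.0)  # treated RTV 1 vs control RTV 10
        assert day == 14

    def test_tgi_bounded_above(self, study):
        for m in study.models:
            _, opt, _ = growth.tgi_curve(study, m)
            assert opt <= 100

    def test_monotone_in_treated_rtv(self):
        control = [[100, 400, 800]] * 3
        slow = [[100, 150, 200]] * 3
        slower = [[100, 120, 130]] * 3
        _, tgi_slow, _ = growth.tgi_curve(two_arm_study(control, slow, self.days), "M1")
        _, tgi_slower, _ = growth.tgi_curve(two_arm_study(control, slower, self.days), "M1")
        assert tgi_slower > tgi_slow

    def test_noise_free_simulation_hits_target(self, noise_free_config):
        study = simulate_growth_study(noise_free_config)
        _, opt, _ = growth.tgi_curve(study, "PDX1")
        assert opt == pytest.approx(65.0, abs=1e-6)

    def test_no_common_day_errors(self):
        rows = [["c1", "M1", "control", 0, 5, 5], ["c2", "M1", "control", 0, 5, 5],
                ["t1", "M1", "treated", 0, 5, 5]]
        study = make_study(rows)
        with pytest.raises(ValueError):
            growth.tgi_curve(study, "M1")


class TestTGITest:
    def test_identical_arm_values_p1(self):
        series = [[100, 200], [100, 200], [100, 200]]
        study = two_arm_study(series, series, [0, 7])
        assert growth.tgi_test(study, "M1", 7) == 1.0

    def test_strong_separation(self):
        control = [[100, 500 + i] for i in range(3)]
        treated = [[100, 100 + i * 0.01] for i in range(3)]
        study = two_arm_study(control, treated, [0, 7])
        assert growth.tgi_test(study, "M1", 7) < 0.001

    def test_matches_exhaustive_permutation(self):
        """t-test p agrees with the exact permutation distribution (<=8 mice)."""
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(10):
            control = [[100.0, 100 * rng.uniform(2, 6)] for _ in range(4)]
            treated = [[100.0, 100 * rng.uniform(1, 4)] for _ in range(4)]
            study = two_arm_study(control, treated, [0, 7])
            p_t = growth.tgi_test(study, "M1", 7)
            df = growth.relative_tumor_volume(study.model_frame("M1"))
            at = df[df["day"] == 7]
            pooled = at["rtv"].to_numpy()
            arms = (at["arm"] == "treated").to_numpy()
            tobs = abs(stats.ttest_ind(pooled[arms], pooled[~arms], equal_var=False).statistic)
            hits = total = 0
            for idx in itertools.combinations(range(8), 4):
                mask = np.zeros(8, bool)
                mask[list(idx)] = True
                t = abs(stats.ttest_ind(pooled[mask], pooled[~mask], equal_var=False).statistic)
                total += 1
                hits += t >= tobs - 1e-12
            worst = max(worst, abs(p_t - hits / total))
        assert worst <= 0.12  # exact-null granularity at n=8 is 1/70


class TestRTVV:
    @pytest.mark.parametrize("vt,vc,expected", [(1000, 1000, 0.0), (400, 1000, -0.6), (800, 1000, -0.2)])
    def test_arithmetic(self, vt, vc, expected):
        assert growth.rtvv(vt, vc) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=25)
    @given(vt=st.floats(1, 1e4), vc=st.floats(1, 1e4), dv=st.floats(1, 100))
    def test_monotone_in_vt_antitone_in_vc(self, vt, vc, dv):
        assert growth.rtvv(vt + dv, vc) > growth.rtvv(vt, vc)
        assert growth.rtvv(vt, vc + dv) < growth.rtvv(vt, vc)

    def test_classification_and_waterfall(self):
        wf = growth.classify_responders({"a": -0.6, "b": -0.4, "c": 0.1})
        assert wf.table.set_index("mouse")["label"].to_dict() == {
            "a": "responder", "b": "non-responder", "c": "non-responder"}
        assert wf.fraction_negative == pytest.approx(2 / 3)
        assert wf.table["rtvv"].is_monotonic_decreasing

    def test_threshold_boundary_is_strict(self):
        wf = growth.classify_responders([-0.5, -0.5, -0.5])
        assert (wf.table["label"] == "non-responder").all()

    def test_arrest_model_all_respond(self, noise_free_config):
        cfg = SimulationConfig(
            **{**noise_free_config.__dict__, "treatment_effect": {"PDX1": 0.0}}
        )
        study = simulate_growth_study(cfg)
        per_mouse = growth.rtvv_table(study, "PDX1")
        wf = growth.classify_responders(per_mouse)
        assert wf.fraction_responding == 1.0


class TestModelCall:
    @pytest.mark.parametrize(
        "tgi,p,expected",
        [(65, 1e-4, "responding"), (49, 0.01, "non-responding"), (80, 0.2, "non-responding")],
    )
    def test_call(self, tgi, p, expected):
        assert growth.model_call(tgi, p) == expected


class TestRelapse:
    def test_identical_arms(self):
        times = {"control": [30, 60, 90, 100], "treated": [30, 60, 90, 100]}
        out = growth.relapse_summary(times, followup_end=120)
        assert out.attrs["logrank_p"] == pytest.approx(1.0)
        assert out["median_time_to_relapse"].nunique() == 1

    def test_complete_separation(self):
        times = {"A": [60.0] * 8, "B": [500.0] * 8}  # B never relapses by day 120
        out = growth.relapse_summary(times, followup_end=120)
        b = out.set_index("arm").loc["B"]
        assert b["n_relapsed"] == 0
        assert np.isnan(b["median_time_to_relapse"])  # never reached
        assert out.attrs["logrank_p"] < 0.01

    def test_exponential_median_ratio(self):
        cfg = SimulationConfig(seed=0, relapse_mice_control=400, relapse_mice_treated=400,
                               relapse_followup=10_000.0)
        times = simulate_relapse(cfg)
        out = growth.relapse_summary(times, followup_end=cfg.relapse_followup).set_index("arm")
        ratio = out.loc["treated", "median_time_to_relapse"] / out.loc["control", "median_time_to_relapse"]
        assert ratio == pytest.approx(116 / 66, rel=0.15)
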