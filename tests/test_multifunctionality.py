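import numpy as np
import pandas as pd
import pytest

from mufunlab import community_metrics as cm
from mufunlab import multifunctionality as mf
from mufunlab.core_io import FunctionObservations
from mufunlab.synthetic_data import (FUNCTIONS, FunctionParams,
                                     ScenarioConfig, gen_dataset)


def _obs(rates, function="scavenging", n_offered=10):
    rows = [{"sample_id": f"s{i}", "function": function,
             "n_offered": n_offered, "n_success": int(round(r * n_offered))}
            for i, r in enumerate(rates)]
    return FunctionObservations(pd.DataFrame(rows))


class TestStandardize:
    def test_top_five_percent_of_ten_is_the_maximum(self):
        std, f_max, flags = mf.standardize(_obs(np.arange(0.1, 1.01, 0.1)))
        assert f_max["scavenging"] == pytest.approx(1.0)
        assert flags          # <20 observations -> flagged fallback

    def test_forty_values_average_top_two(self):
        rates = [0.9, 0.8] + [0.5] * 38
        std, f_max, flags = mf.standardize(_obs(rates))
        assert f_max["scavenging"] == pytest.approx(0.85)
        assert not flags

    def test_rates_above_fmax_clip_to_one(self):
        rates = [1.0, 0.7] + [0.5] * 38
        std, f_max, _ = mf.standardize(_obs(rates))
        assert f_max["scavenging"] == pytest.approx(0.85)
        assert std["F_std"].max() == pytest.approx(1.0)

    def test_all_zero_function_is_error_naming_it(self):
        with pytest.raises(mf.MultifunctionalityError, match="granivory"):
            mf.standardize(_obs([0.0] * 25, function="granivory"))


class TestEffectiveMF:
    def _std(self, values):
        rows = [{"sample_id": "s0", "function": fn, "F_std": v}
                for fn, v in zip(FUNCTIONS, values)]
        return pd.DataFrame(rows)

    def test_even_functions_give_qn_nfunctions_and_mq_equals_mean(self):
        emf = mf.effective_mf(self._std([0.5, 0.5, 0.5, 0.5]))
        row = emf.table.loc["s0"]
        assert row["qN"] == pytest.approx(4.0)
        assert row["M_q"] == pytest.approx(0.5)
        assert row["M_q"] == pytest.approx(row["A"])

    def test_single_performing_function(self):
        emf = mf.effective_mf(self._std([1.0, 0.0, 0.0, 0.0]))
        row = emf.table.loc["s0"]
        assert row["qN"] == pytest.approx(1.0)
        assert row["M_q"] == pytest.approx(0.0625)

    def test_hill_order_monotonicity(self):
        vals = [0.9, 0.5, 0.3, 0.1]
        qns = [mf.effective_mf(self._std(vals), q=q).table.loc["s0", "qN"]
               for q in (0.0, 1.0, 2.0)]
        assert qns[0] >= qns[1] >= qns[2]

    def test_all_zero_sample_flagged_mq_zero(self):
        emf = mf.effective_mf(self._std([0.0, 0.0, 0.0, 0.0]))
        assert emf.table.loc["s0", "M_q"] == 0.0
        assert emf.flags


def test_functions_above_threshold_nonincreasing(std_rates):
    m = mf.functions_above_threshold(std_rates)
    diffs = np.diff(m.to_numpy(), axis=1)
    assert (diffs <= 0).all()
    assert m.to_numpy().min() >= 0 and m.to_numpy().max() <= 4


class TestReciprocalSlope:
    def test_printed_control_slope(self):
        assert mf.species_per_function(0.09) == pytest.approx(11.1, abs=0.05)

    def test_printed_suppression_slope(self):
        assert mf.species_per_function(0.12) == pytest.approx(8.3, abs=0.05)

    def test_identity_with_rmde(self):
        for r in (0.03, 0.09, 0.5):
            assert mf.species_per_function(r) * r == pytest.approx(1.0)

    def test_zero_slope_rejected(self):
        with pytest.raises(mf.MultifunctionalityError):
            mf.species_per_function(0.0)


class TestThresholdSweep:
    def test_planted_diversity_effect_detected(self, dataset, std_rates,
                                               profiles):
        curves = mf.threshold_sweep(std_rates, profiles, dataset.design)
        assert set(curves) == {"control", "suppression"}
        c = curves["suppression"]
        assert c.t_min is not None
        assert c.t_min <= c.t_mde <= c.t_max
        assert c.r_mde > 0
        assert c.species_per_function == pytest.approx(1 / c.r_mde)
        assert c.curve["threshold"].tolist() == list(range(5, 96))

    def test_degenerate_thresholds_flagged_zero_slope(self, dataset,
                                                      std_rates, profiles):
        curves = mf.threshold_sweep(std_rates, profiles, dataset.design,
                                    thresholds=np.array([0]))
        for c in curves.values():     # every sample performs all 4 functions
            row = c.curve.iloc[0]
            assert row["beta"] == 0.0 and row["flag"] == "degenerate"

    def test_mde_test_detects_planted_uniform_effect(self):
        fns = {f: FunctionParams(-0.2, 0.08, 0.5) for f in FUNCTIONS}
        ds = gen_dataset(ScenarioConfig(seed=21, functions=fns))
        std, *_ = mf.standardize(ds.functions)
        prof = cm.diversity_profile(ds.community)
        curves = mf.threshold_sweep(std, prof, ds.design)
        res = mf.mde_test(std, ds.design, curves)
        assert res.z > 1.96

    def test_mde_test_requires_defined_tmde(self, dataset, std_rates):
        broken = {"control": mf.ThresholdCurve("control", pd.DataFrame(),
                                               None, None, None, None)}
        with pytest.raises(mf.MultifunctionalityError):
            mf.mde_test(std_rates, dataset.design, broken)


class TestFunctionCovariance:
    def test_self_correlation_is_one(self, dataset, std_rates):
        tab = mf.function_covariance(std_rates, dataset.design, n_perm=49)
        self_rows = tab[tab["f1"] == tab["f2"]]
        assert (self_rows["correlation"] == 1.0).all()
        assert tab["correlation"].abs().max() <= 1.0

    def test_planted_negative_granivory_protection(self):
        # strong planted negative correlation expresses in the rates
        corr = np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                         [0, 0, 1, -0.8], [0, 0, -0.8, 1.0]])
        neg = 0
        for seed in range(5):
            ds = gen_dataset(ScenarioConfig(seed=seed, function_corr=corr,
                                            noise_sd=0.5))
            std, *_ = mf.standardize(ds.functions)
            tab = mf.function_covariance(std, ds.design, n_perm=49, seed=seed)
            pair = tab[(tab.f1 == "granivory") &
                       (tab.f2 == "plant_protection")]
            neg += (pair["correlation"] < 0).all()
        assert neg >= 4

    def test_zero_variance_function_flagged(self, dataset):
        std = pd.DataFrame({
            "sample_id": list(dataset.community.counts.index[:6]) * 2,
            "function": ["scavenging"] * 6 + ["granivory"] * 6,
            "F_std": [0.5] * 6 + [0.1, 0.4, 0.2, 0.6, 0.3, 0.2]})
        tab = mf.function_covariance(std, dataset.design, by_treatment=False,
                                     n_perm=9)
        flagged = tab[(tab.f1 == "scavenging") & (tab.f2 == "granivory")]
        assert (flagged["flag"] == "zero variance").all()
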