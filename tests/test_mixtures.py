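import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from odorint.exceptions import MissingParameterError, UnsupportedSizeError
from odorint.mixtures import (
    MODELS,
    ComponentState,
    MixtureModelConfig,
    MixtureSpec,
    predict_add,
    predict_all,
    predict_cb,
    predict_euc,
    predict_pri,
    predict_sc,
    predict_u,
    predict_vec,
)
from odorint.psychophysics import HillParams, hill_intensity

CFG = MixtureModelConfig()


def mix_of(*intensities, concs=None, hills=None, mid="m"):
    comps = []
    for i, inten in enumerate(intensities):
        comps.append(
            ComponentState(
                f"c{i}",
                concentration=concs[i] if concs else 1.0,
                intensity_alone=float(inten),
                hill=hills[i] if hills else None,
            )
        )
    return MixtureSpec(mid, tuple(comps))


intensity_lists = st.lists(
    st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=1, max_size=10
)


class TestSimpleAndGeometric:
    @pytest.mark.parametrize(
        "fn,intensities,expected",
        [
            (predict_add, (2, 3, 4), 9.0),
            (predict_add, (7,), 7.0),
            (predict_add, (0, 0, 0), 0.0),
            (predict_sc, (2, 3, 4), 4.0),
            (predict_sc, (7,), 7.0),
            (predict_sc, (4, 4), 4.0),
            (predict_euc, (3, 4), 5.0),
            (predict_euc, (7,), 7.0),
            (predict_euc, (1, 1, 1, 1), 2.0),
        ],
    )
    def test_known_values(self, fn, intensities, expected):
        pred = fn(mix_of(*intensities))
        assert pred.valid
        assert pred.value == pytest.approx(expected, rel=1e-12)

    def test_vec_pair(self):
        pred = predict_vec(mix_of(3, 4), CFG)
        assert pred.value == pytest.approx(math.sqrt(17.8), rel=1e-12)

    def test_vec_zero_cosine_reduces_to_euc(self):
        cfg = MixtureModelConfig(cos_alpha=0.0)
        assert predict_vec(mix_of(3, 4), cfg).value == pytest.approx(5.0)

    def test_vec_imaginary_intensity_flagged(self):
        pred = predict_vec(mix_of(*([1.0] * 10)), CFG)
        assert not pred.valid
        assert math.isnan(pred.value)

    def test_u_pair(self):
        pred = predict_u(mix_of(3, 4), CFG)
        assert pred.value == pytest.approx(math.sqrt(25 - 0.6 * math.sqrt(12)), rel=1e-12)

    def test_u_triple_matches_bruteforce(self):
        pred = predict_u(mix_of(2, 2, 2), CFG)
        assert pred.value == pytest.approx(oracles.oracle_u([2, 2, 2], -0.3), rel=1e-12)

    def test_u_too_many_components(self):
        with pytest.raises(UnsupportedSizeError):
            predict_u(mix_of(*range(1, 14)), CFG)

    @given(vals=intensity_lists)
    @settings(max_examples=100, deadline=None)
    def test_u_zero_cosine_equals_euc(self, vals):
        cfg = MixtureModelConfig(cos_alpha=0.0)
        u = predict_u(mix_of(*vals), cfg).value
        euc = predict_euc(mix_of(*vals)).value
        assert u == pytest.approx(euc, abs=1e-12)

    @given(vals=intensity_lists)
    @settings(max_examples=100, deadline=None)
    def test_sc_le_euc_le_add(self, vals):
        m = mix_of(*vals)
        sc, euc, add = predict_sc(m).value, predict_euc(m).value, predict_add(m).value
        assert sc <= euc + 1e-9 <= add + 2e-9


class TestBiophysical:
    def test_cb_single_component_half_max(self):
        hp = HillParams(100.0, 1e-6, 1.0)
        m = mix_of(0, concs=[1e-6], hills=[hp])
        assert predict_cb(m, CFG).value == pytest.approx(50.0, rel=1e-12)

    def test_cb_two_components(self):
        hills = [HillParams(100, 1e-6, 1), HillParams(50, 1e-5, 1)]
        m = mix_of(0, 0, concs=[1e-6, 1e-5], hills=hills)
        assert predict_cb(m, CFG).value == pytest.approx(50.0, rel=1e-12)

    def test_cb_zero_concentration_inert(self):
        hills = [HillParams(100, 1e-6, 1), HillParams(50, 1e-5, 2)]
        full = mix_of(0, 0, concs=[1e-6, 0.0], hills=hills)
        alone = mix_of(0, concs=[1e-6], hills=hills[:1])
        assert predict_cb(full, CFG).value == pytest.approx(predict_cb(alone, CFG).value)

    def test_cb_missing_hill(self):
        with pytest.raises(MissingParameterError, match="c1"):
            predict_cb(mix_of(1, 2, hills=[HillParams(10, 1e-6, 1), None]), CFG)

    def test_pri_single_component(self):
        hp = HillParams(25.0, 1e-6, 1.0)
        m = mix_of(0, concs=[5e-6], hills=[hp])
        expected = hill_intensity(hp, 0.2 * 5e-6)
        assert predict_pri(m, CFG).value == pytest.approx(expected, rel=1e-12)

    def test_pri_two_equal_components(self):
        # both components contribute I(0.2C) = 10, giving 10 + ln 2
        hp = HillParams(20.0, 1e-6, 1.0)
        m = mix_of(0, 0, concs=[5e-6, 5e-6], hills=[hp, hp])
        assert predict_pri(m, CFG).value == pytest.approx(10 + math.log(2), rel=1e-9)

    def test_pri_dominates_max(self):
        hills = [HillParams(40, 1e-7, 2), HillParams(70, 1e-6, 1)]
        m = mix_of(0, 0, concs=[3e-7, 2e-6], hills=hills)
        parts = [hill_intensity(h, 0.2 * c) for h, c in zip(hills, [3e-7, 2e-6])]
        assert predict_pri(m, CFG).value >= max(parts)

    def test_pri_prunes_zero_concentration(self):
        hills = [HillParams(40, 1e-7, 2), HillParams(70, 1e-6, 1)]
        with_zero = mix_of(0, 0, concs=[3e-7, 0.0], hills=hills)
        without = mix_of(0, concs=[3e-7], hills=hills[:1])
        assert predict_pri(with_zero, CFG).value == pytest.approx(
            predict_pri(without, CFG).value
        )

    def test_pri_all_zero_concentration(self):
        with pytest.raises(ValueError):
            predict_pri(mix_of(0, concs=[0.0], hills=[HillParams(1, 1e-6, 1)]), CFG)


class TestPredictAll:
    def test_full_hill_mixture_all_valid(self):
        hills = [HillParams(80, 1e-6, 1.5), HillParams(60, 1e-7, 2.0)]
        m = mix_of(30, 40, concs=[1e-6, 1e-7], hills=hills)
        preds = predict_all(m, CFG)
        assert [p.model for p in preds] == list(MODELS)
        assert all(p.valid for p in preds)

    def test_missing_hill_flags_cb_pri(self):
        preds = {p.model: p for p in predict_all(mix_of(3, 4), CFG)}
        assert not preds["CB"].valid and "Hill" in preds["CB"].reason
        assert not preds["PRI"].valid
        assert preds["ADD"].valid

    def test_ten_equal_components_vec_invalid_others_valid(self):
        # VEC's radicand is negative for any ten equal intensities at
        # cos_alpha=-0.3; the other models stay defined at this magnitude
        hp = HillParams(90, 1e-6, 1)
        m = mix_of(*([80.0] * 10), concs=[1e-6] * 10, hills=[hp] * 10)
        preds = {p.model: p for p in predict_all(m, CFG)}
        assert not preds["VEC"].valid
        for name in ("ADD", "SC", "EUC", "U", "CB", "PRI"):
            assert preds[name].valid, name

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            predict_all(mix_of(1), CFG, models=["XYZ"])


class TestSpecInvariants:
    def test_single_component_consistency(self):
        hp = HillParams(80.0, 1e-6, 1.0)
        c = 2e-6
        alone = hill_intensity(hp, c)
        m = mix_of(alone, concs=[c], hills=[hp])
        assert predict_add(m).value == alone
        assert predict_sc(m).value == alone
        assert predict_euc(m).value == alone
        assert predict_cb(m, CFG).value == pytest.approx(alone, rel=1e-12)
        assert predict_pri(m, CFG).value == pytest.approx(hill_intensity(hp, 0.2 * c))

    def test_duplicate_component_ids_rejected(self):
        with pytest.raises(ValueError):
            MixtureSpec("m", (ComponentState("a"), ComponentState("a")))

    def test_monotonicity_in_intensity(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            vals = rng.uniform(0, 50, rng.integers(2, 8))
            bumped = vals.copy()
            j = rng.integers(len(vals))
            bumped[j] += rng.uniform(0, 20)
            for fn in (predict_add, predict_sc, predict_euc):
                assert fn(mix_of(*bumped)).value >= fn(mix_of(*vals)).value - 1e-9
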