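"""Phenology response functions, the four predictors, ensemble, windows."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenohydro as ph
from phenohydro.phenology_models import (CHILL_LEAD_DAYS, AlternatingParams,
                                         EnsembleWeights, M1Params,
                                         SeasonInputs, SeasonMatrix,
                                         UnichillParams, UniforcParams,
                                         chilling_response,
                                         derive_stage_windows, forcing_gdd,
                                         forcing_sigmoid, predict_alternating,
                                         predict_batch, predict_ensemble,
                                         predict_m1, predict_unichill,
                                         predict_uniforc, round_half_away)

from oracles import (oracle_alternating, oracle_m1, oracle_unichill,
                     oracle_uniforc)


def _season(tmean, lat=35.0, year=2015):
    return SeasonInputs(np.asarray(tmean, dtype=float), lat, year)


def _const_season(value, lat=35.0, ndays=365):
    return _season(np.full(CHILL_LEAD_DAYS + ndays, float(value)), lat)


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

def test_forcing_gdd_piecewise():
    assert forcing_gdd(5.0, 5.0) == 0.0
    assert forcing_gdd(10.0, 5.0) == 5.0
    assert forcing_gdd(2.0, 5.0) == 0.0


def test_forcing_sigmoid_shape():
    assert forcing_sigmoid(10.0, -0.5, 10.0) == pytest.approx(0.5)
    assert forcing_sigmoid(25.0, 0.0, 10.0) == pytest.approx(0.5)
    assert forcing_sigmoid(30.0, -1.0, 10.0) == pytest.approx(
        1.0 / (1.0 + math.exp(-20.0)), abs=1e-8)
    t = np.linspace(-40, 50, 500)
    assert np.all(np.diff(forcing_sigmoid(t, -0.3, 8.0)) > 0)


def test_chilling_response_bell():
    assert chilling_response(2.0, 0.5, 0.0, 2.0) == pytest.approx(0.5)
    # even symmetry when the linear term vanishes
    assert chilling_response(7.0, 1.0, 0.0, 2.0) == pytest.approx(
        chilling_response(-3.0, 1.0, 0.0, 2.0))
    assert chilling_response(12.0, 0.1, 0.0, 2.0) == pytest.approx(
        1.0 / (1.0 + math.exp(10.0)), rel=1e-6)


@given(t=st.floats(-40, 50), b=st.floats(-5, 0), c=st.floats(-5, 20),
       a_c=st.floats(1e-3, 2), b_c=st.floats(-2, 2))
@settings(max_examples=200, deadline=None)
def test_rates_finite_and_in_range(t, b, c, a_c, b_c):
    r1 = forcing_sigmoid(t, b, c)
    r2 = chilling_response(t, a_c, b_c, c)
    r3 = forcing_gdd(t, c)
    assert 0.0 <= r1 <= 1.0 and np.isfinite(r1)
    assert 0.0 <= r2 <= 1.0 and np.isfinite(r2)
    assert r3 >= 0.0 and np.isfinite(r3)


# ---------------------------------------------------------------------------
# predictors: closed-form cases
# ---------------------------------------------------------------------------

def test_m1_unit_rate_accumulation():
    # T one degree above base, k=0: one forcing unit per day
    season = _const_season(6.0)
    assert predict_m1(season, M1Params(t1=1, threshold=5.0, f_star=10.0,
                                       k=0.0)) == 10


def test_m1_k_zero_reduces_to_gdd():
    rng = np.random.default_rng(5)
    temps = rng.uniform(-5, 25, CHILL_LEAD_DAYS + 365)
    season = _season(temps)
    p = M1Params(t1=30, threshold=4.0, f_star=120.0, k=0.0)
    got = predict_m1(season, p)
    acc, expect = 0.0, None
    for i in range(29, 365):
        acc += max(temps[CHILL_LEAD_DAYS + i] - 4.0, 0.0)
        if acc >= 120.0:
            expect = i + 1
            break
    assert got == expect


def test_uniforc_constant_rate():
    season = _const_season(10.0)  # rate exactly 0.5 at the midpoint
    assert predict_uniforc(season, UniforcParams(t1=1, f_star=5.0, b=-0.3,
                                                 c=10.0)) == 10


def test_uniforc_unreachable_requirement():
    season = _const_season(30.0)
    assert predict_uniforc(season, UniforcParams(t1=1, f_star=400.0, b=-0.3,
                                                 c=10.0)) is None


def test_alternating_decoupled_limit():
    # c = 0 freezes the requirement at a + b; unit forcing rate
    season = _const_season(6.0)
    p = AlternatingParams(t1=20, threshold=5.0, a=2.0, b=1.0, c=0.0)
    assert predict_alternating(season, p) == 20 - 1 + math.ceil(3.0)


def test_alternating_more_chill_never_delays():
    rng = np.random.default_rng(9)
    temps = rng.uniform(0, 15, CHILL_LEAD_DAYS + 365)
    p = AlternatingParams(t1=32, threshold=7.0, a=30.0, b=300.0, c=-0.02)
    base = predict_alternating(_season(temps), p)
    colder = temps.copy()
    colder[:CHILL_LEAD_DAYS] -= 10.0  # extra chill days before forcing starts
    more = predict_alternating(_season(colder), p)
    if base is not None and more is not None:
        assert more <= base


def test_unichill_constant_rate_arithmetic():
    season = _const_season(2.0, ndays=365)
    # chilling rate exactly 0.5 at the optimum; forcing rate 0.5 at its
    # midpoint: t_c = 10th day of chilling, flowering 10 days after t_c
    p = UnichillParams(t0=130, c_star=5.0, f_star=5.0, b_f=-0.4, c_f=2.0,
                       a_c=0.5, b_c=0.0, c_c=2.0)
    # t0=130 -> chilling starts index 129; t_c index 138; forcing 139..148;
    # flowering index 148 -> DOY 148 - 122 + 1 = 27
    assert predict_unichill(season, p) == 27


def test_unichill_no_chilling_reduces_to_uniforc():
    rng = np.random.default_rng(11)
    temps = rng.uniform(-5, 25, CHILL_LEAD_DAYS + 365)
    season = _season(temps)
    p = UnichillParams(t0=CHILL_LEAD_DAYS + 40, c_star=0.0, f_star=12.0,
                       b_f=-0.3, c_f=8.0, a_c=0.1, b_c=0.0, c_c=2.0)
    uf = UniforcParams(t1=40, f_star=12.0, b=-0.3, c=8.0)
    assert predict_unichill(season, p) == predict_uniforc(season, uf)


def test_forcing_models_warming_never_delays(rng):
    for _ in range(25):
        temps = rng.uniform(-10, 25, CHILL_LEAD_DAYS + 365)
        m1 = M1Params(t1=40, threshold=5.0, f_star=80.0, k=0.6)
        uf = UniforcParams(t1=40, f_star=15.0, b=-0.3, c=10.0)
        warm = temps + 1.0
        for predict, p in ((predict_m1, m1), (predict_uniforc, uf)):
            a = predict(_season(temps), p)
            b = predict(_season(warm), p)
            if a is not None:
                assert b is not None and b <= a


# ---------------------------------------------------------------------------
# oracle equivalence on random series
# ---------------------------------------------------------------------------

def _random_params(model_id, rng):
    if model_id == "m1":
        return M1Params(t1=rng.uniform(1, 120), threshold=rng.uniform(-5, 15),
                        f_star=rng.uniform(10, 200), k=rng.uniform(0, 2))
    if model_id == "uniforc":
        return UniforcParams(t1=rng.uniform(1, 120),
                             f_star=rng.uniform(5, 120),
                             b=rng.uniform(-3, -0.05),
                             c=rng.uniform(0, 18))
    if model_id == "alternating":
        return AlternatingParams(t1=rng.uniform(1, 120),
                                 threshold=rng.uniform(-2, 12),
                                 a=rng.uniform(0, 200),
                                 b=rng.uniform(0, 800),
                                 c=rng.uniform(-0.08, 0))
    return UnichillParams(t0=rng.uniform(1, 140), c_star=rng.uniform(1, 100),
                          f_star=rng.uniform(5, 100),
                          b_f=rng.uniform(-3, -0.05),
                          c_f=rng.uniform(0, 18),
                          a_c=rng.uniform(1e-3, 1.5),
                          b_c=rng.uniform(-1.5, 1.5),
                          c_c=rng.uniform(-5, 15))


ORACLES = {"m1": None, "uniforc": oracle_uniforc,
           "alternating": oracle_alternating, "unichill": oracle_unichill}


@pytest.mark.parametrize("model_id", ["m1", "uniforc", "alternating",
                                      "unichill"])
def test_predictors_match_bruteforce_oracle(model_id):
    rng = np.random.default_rng(ord(model_id[0]))
    predict = ph.__dict__[f"predict_{model_id}"]
    for trial in range(100):
        ndays = 365 if trial % 3 else 366
        temps = rng.uniform(-15, 28, CHILL_LEAD_DAYS + ndays)
        lat = rng.uniform(27, 44)
        p = _random_params(model_id, rng)
        got = predict(_season(temps, lat=lat), p)
        if model_id == "m1":
            expect = oracle_m1(list(temps), lat, p)
        else:
            expect = ORACLES[model_id](list(temps), p)
        assert got == expect, f"trial {trial}: {got} != {expect} for {p}"


def test_batch_agrees_with_single_predictions(rng):
    seasons = [_season(rng.uniform(-10, 25, CHILL_LEAD_DAYS + n), lat)
               for n, lat in [(365, 30.0), (366, 35.0), (365, 42.0)]]
    p = UniforcParams(t1=50, f_star=20.0, b=-0.25, c=10.0)
    batch = predict_batch("uniforc", p, SeasonMatrix(seasons))
    singles = [predict_uniforc(s, p) for s in seasons]
    for b, s in zip(batch, singles):
        assert (np.isnan(b) and s is None) or int(b) == s


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

def _weights(ws, rs):
    return EnsembleWeights(dict(zip("abcd", ws)), dict(zip("abcd", rs)))


def test_ensemble_consensus_and_mean():
    w = _weights([0.25] * 4, [5.0] * 4)
    assert predict_ensemble(dict(zip("abcd", [100] * 4)), w) == 100
    w2 = EnsembleWeights({"a": 0.5, "b": 0.5}, {"a": 3.0, "b": 3.0})
    assert predict_ensemble({"a": 100, "b": 110}, w2) == 105


def test_ensemble_weighted_mean_rounding():
    # normalised inverse-RMSE weights for RMSEs (5.21, 6.88, 6.97, 9.71)
    rs = [5.21, 6.88, 6.97, 9.71]
    inv = [1.0 / r for r in rs]
    ws = [v / sum(inv) for v in inv]
    w = _weights(ws, rs)
    preds = dict(zip("abcd", [94, 100, 104, 110]))
    mean = sum(wi * pi for wi, pi in zip(ws, [94, 100, 104, 110]))
    assert predict_ensemble(preds, w) == round_half_away(mean)
    assert predict_ensemble(preds, w) == 101  # frozen independent arithmetic


def test_ensemble_drops_failed_members():
    w = _weights([0.4, 0.3, 0.2, 0.1], [2.0, 3.0, 4.0, 5.0])
    preds = {"a": 100, "b": None, "c": 104, "d": None}
    expect = round_half_away((0.4 * 100 + 0.2 * 104) / 0.6)
    assert predict_ensemble(preds, w) == expect
    assert predict_ensemble({k: None for k in "abcd"}, w) is None


def test_round_half_away():
    assert round_half_away(100.5) == 101
    assert round_half_away(99.5) == 100
    assert round_half_away(100.49) == 100


def test_weights_container_invariants():
    with pytest.raises(ValueError):
        _weights([0.5, 0.2, 0.2, 0.2], [5, 6, 7, 8])  # sum != 1
    with pytest.raises(ValueError):
        # larger RMSE paired with the larger weight
        EnsembleWeights({"a": 0.7, "b": 0.3}, {"a": 9.0, "b": 2.0})


# ---------------------------------------------------------------------------
# stage windows
# ---------------------------------------------------------------------------

def test_stage_windows_worked_example():
    w = derive_stage_windows(93, (30, 102, 39))
    assert w.fruit_set == 123
    w2 = derive_stage_windows(94, (25, 102, 39))
    assert w2.fruit_set == 119
    assert w2.spans()["fruit_expansion"][0] == 120


def test_stage_windows_chaining_arithmetic():
    w = derive_stage_windows(100, (22, 102, 39))
    assert w.maturity == 263
    spans = w.spans()
    assert spans["flowering_fruit_set"] == (100, 122)
    assert spans["fruit_expansion"] == (123, 224)
    assert spans["coloring_maturity"] == (225, 263)
    # stages abut with no gap or overlap
    assert spans["fruit_expansion"][0] == spans["flowering_fruit_set"][1] + 1
    assert spans["coloring_maturity"][0] == spans["fruit_expansion"][1] + 1


def test_stage_windows_overrun_rejected():
    with pytest.raises(ValueError, match="overruns"):
        derive_stage_windows(210, (22, 102, 39))
    with pytest.raises(ValueError):
        derive_stage_windows(100, (0, 102, 39))
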