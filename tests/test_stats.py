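"""One-way ANOVA against hand-worked tables, scipy/statsmodels oracles and
calibration on the generator."""

import numpy as np
import pytest
from scipy import stats as sp_stats

import semgfog as sf
from semgfog import _intervals
from semgfog.fog_detect import PrecursorEvent
from semgfog.stats import StateSamples, one_way_anova


def test_identical_groups_give_f_zero():
    r = one_way_anova(StateSamples({"a": [1, 2, 3], "b": [1, 2, 3]}))
    assert r.F == 0.0
    assert r.p == 1.0


def test_hand_worked_table():
    # groups {2,3,4} and {6,7,8}: SS_between = 24 (df 1), SS_within = 4 (df 4)
    # -> MS_between = 24, MS_within = 1, F = 24
    r = one_way_anova(StateSamples({"a": [2, 3, 4], "b": [6, 7, 8]}))
    assert r.F == pytest.approx(24.0, abs=1e-12)
    assert r.df_between == 1 and r.df_within == 4
    assert r.p == pytest.approx(float(sp_stats.f.sf(24.0, 1, 4)), rel=1e-12)


def test_matches_scipy_and_statsmodels(rng):
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    groups = [rng.normal(loc=i * 0.3, size=rng.integers(5, 15)) for i in range(3)]
    r = one_way_anova(StateSamples({f"g{i}": g for i, g in enumerate(groups)}))
    F_sp, p_sp = sp_stats.f_oneway(*groups)
    assert r.F == pytest.approx(float(F_sp), rel=1e-10)
    assert r.p == pytest.approx(float(p_sp), rel=1e-10)
    df = pd.DataFrame({
        "y": np.concatenate(groups),
        "g": np.repeat([f"g{i}" for i in range(3)], [len(g) for g in groups]),
    })
    table = sm.stats.anova_lm(ols("y ~ C(g)", data=df).fit())
    assert r.F == pytest.approx(float(table["F"].iloc[0]), rel=1e-8)


def test_two_group_f_equals_t_squared(rng):
    a = rng.normal(size=12)
    b = rng.normal(loc=0.5, size=9)
    r = one_way_anova(StateSamples({"a": a, "b": b}))
    t, p = sp_stats.ttest_ind(a, b)
    assert r.F == pytest.approx(float(t) ** 2, rel=1e-10)
    assert r.p == pytest.approx(float(p), rel=1e-10)


def test_shift_and_scale_invariance(rng):
    groups = {f"g{i}": rng.normal(size=8) for i in range(3)}
    base = one_way_anova(StateSamples(groups))
    shifted = one_way_anova(StateSamples({k: v + 17.0 for k, v in groups.items()}))
    scaled = one_way_anova(StateSamples({k: 4.0 * v for k, v in groups.items()}))
    assert shifted.F == pytest.approx(base.F, rel=1e-9)
    assert scaled.F == pytest.approx(base.F, rel=1e-9)


def test_degenerate_zero_within_variance():
    r = one_way_anova(StateSamples({"a": [1.0, 1.0], "b": [2.0, 2.0]}))
    assert r.degenerate and r.p == 0.0
    flat = one_way_anova(StateSamples({"a": [1.0, 1.0], "b": [1.0, 1.0]}))
    assert flat.degenerate and flat.p == 1.0


def test_group_validation():
    with pytest.raises(ValueError):
        StateSamples({"only": [1.0, 2.0]})
    with pytest.raises(ValueError):
        StateSamples({"a": [1.0], "b": [1.0, 2.0]})


def test_curl_active_vs_pause_significant():
    hits = 0
    for seed in range(10):
        rec, track = sf.generate_curl_session(seed=5000 + seed)
        env = sf.sliding_features(rec, 0.2, 0.01)
        comp = sf.state_comparison(env, track, states=("active", "pause"))
        hits += comp.anova.p < 0.05
        assert comp.mean_ratio > 1.0
    assert hits == 10


def test_precursor_vs_normal_ratio_on_cohort():
    rec, track = sf.default_cohort()[0]
    res = sf.analyze_session(rec, track)
    comp = sf.state_comparison(res.envelope, track, states=("normal", "precursor"),
                               events=res.events)
    assert comp.mean_ratio == pytest.approx(3.0, rel=0.15)
    assert comp.anova.p < 0.001


def test_episode_unit_uses_interval_means():
    rec, track = sf.default_cohort()[1]
    res = sf.analyze_session(rec, track)
    comp = sf.state_comparison(res.envelope, track, states=("normal", "precursor"),
                               unit="episode", events=res.events)
    assert comp.samples.groups["precursor"].size == 2  # one mean per episode
    assert comp.mean_ratio > 2.0


def test_null_pvalues_uniform_with_matched_spans():
    """Attenuation-1.0 control: episode-level p-values follow U(0,1)."""
    ps = []
    for seed in range(500, 560):
        eps = [sf.FogEpisodeSpec(20.0, attenuation=1.0),
               sf.FogEpisodeSpec(35.0, attenuation=1.0)]
        rec, track = sf.generate_session(sf.SessionSpec(duration_s=55.0,
                                                        episodes=eps, seed=seed))
        env = sf.sliding_features(sf.bandpass(rec), 0.2, 0.01)
        rms = env.rms_mv[0]
        pre = [e.span() for e in eps]
        ref = [(2.0, 11.0), (42.0, 51.0)]  # length-matched normal spans

        def interval_means(iv):
            return [rms[_intervals.windows_inside(env.times, env.window_s, [x])].mean()
                    for x in iv]

        r = one_way_anova(StateSamples({"pre": interval_means(pre),
                                        "ref": interval_means(ref)}))
        ps.append(r.p)
    assert sp_stats.kstest(ps, "uniform").pvalue > 0.01
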