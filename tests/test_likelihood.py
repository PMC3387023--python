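"""Trial-type classification, Monte-Carlo predictions, likelihoods, fitting."""
import numpy as np
import pytest

import vpchange as vp
from vpchange.likelihood import classify_table


def _row(delta, change, loc, rels):
    row = {"delta": delta, "change": change, "change_location": loc}
    for i, r in enumerate(rels, start=1):
        row[f"rel_{i}"] = r
    return row


def test_classify_trial_examples():
    t = vp.classify_trial(_row(0.0, 0, 0, "HHLL"))
    assert t == vp.TrialType(0, 2, "low")  # no-change convention
    t = vp.classify_trial(_row(44.0, 1, 2, "HHHH"))
    assert t == vp.TrialType(15, 4, "high")  # 44 deg -> nearest multiple 45
    t = vp.classify_trial(_row(-1.4, 1, 1, "LLLL"))
    assert t == vp.TrialType(0, 0, "low")
    t = vp.classify_trial(_row(89.9, 1, 4, "LLLH"))
    assert t == vp.TrialType(30, 1, "high")


def test_type_space_has_310_cells():
    types = vp.all_trial_types()
    assert len(types) == 310
    assert len({t.index for t in types}) == 310
    assert vp.N_TRIAL_TYPES == 310


def test_classify_table_matches_scalar(small_eeo_dataset):
    cells = classify_table(small_eeo_dataset)
    expected = [vp.classify_trial(row).index
                for _, row in small_eeo_dataset.iterrows()]
    assert list(cells) == expected


def test_prediction_table_bounds_and_structure(eeo_params):
    spec = vp.parse_model_code("EEO")
    tab = vp.predict_table(spec, eeo_params, n_samples=400, seed=0)
    eps = 1.0 / 800
    probs = tab.probs
    finite = np.isfinite(probs)
    assert np.all(probs[finite] >= eps) and np.all(probs[finite] <= 1 - eps)
    # unreachable cells are flagged, e.g. a high-reliability change with N_H=0
    assert np.isnan(probs[vp.TrialType(5, 0, "high").index])
    assert np.isnan(probs[vp.TrialType(5, 4, "low").index])
    frame = tab.to_frame()
    assert len(frame) == 310


def test_prediction_high_precision_limit():
    spec = vp.parse_model_code("EEO")
    tab = vp.predict_table(spec, {"J_low": 3000.0, "J_high": 3000.0,
                                  "p_change": 0.5}, n_samples=400, seed=1)
    for h in range(5):
        assert tab.prob(vp.TrialType(30, h, "high" if h else "low")) > 0.99
        # bin-0 cells are the model's false-alarm probability
        assert tab.prob(vp.TrialType(0, h, "low")) < 0.05


def test_prediction_monotone_in_magnitude():
    spec = vp.parse_model_code("VVO")
    tab = vp.predict_table(spec, vp.representative_params(spec),
                           n_samples=600, seed=2)
    for h in range(5):
        rel = "high" if h > 0 else "low"
        p = np.array([tab.prob(vp.TrialType(b, h, rel)) for b in range(31)])
        assert np.all(np.diff(p) > -0.06)  # non-decreasing within MC error


def test_log_likelihood_single_trial_and_additivity(small_eeo_dataset, eeo_params):
    spec = vp.parse_model_code("EEO")
    one = small_eeo_dataset.iloc[[0]]
    tab = vp.predict_table(spec, eeo_params, n_samples=300, seed=5)
    p = tab.prob(vp.classify_trial(one.iloc[0]))
    expected = np.log(p if one.iloc[0]["response"] == "change" else 1 - p)
    ll = vp.log_likelihood(one, spec, eeo_params, n_samples=300, seed=5)
    assert ll == pytest.approx(expected, rel=1e-12)
    # duplicating every trial doubles the log-likelihood
    import pandas as pd
    doubled = pd.concat([small_eeo_dataset, small_eeo_dataset], ignore_index=True)
    ll1 = vp.log_likelihood(small_eeo_dataset, spec, eeo_params, 300, seed=5)
    ll2 = vp.log_likelihood(doubled, spec, eeo_params, 300, seed=5)
    assert ll2 == pytest.approx(2 * ll1, rel=1e-12)


def test_log_likelihood_deterministic_given_seed(small_eeo_dataset, eeo_params):
    spec = vp.parse_model_code("EEO")
    a = vp.log_likelihood(small_eeo_dataset, spec, eeo_params, 200, seed=7)
    b = vp.log_likelihood(small_eeo_dataset, spec, eeo_params, 200, seed=7)
    assert a == b


def test_log_likelihood_requires_responses(eeo_params):
    trials = vp.generate_trials(10, np.random.default_rng(0))
    with pytest.raises(ValueError):
        vp.log_likelihood(trials, vp.parse_model_code("EEO"), eeo_params, 100)


def test_fit_single_point_grid(small_eeo_dataset, eeo_params):
    spec = vp.parse_model_code("EEO")
    grid = {n: np.array([v]) for n, v in eeo_params.items()}
    fit = vp.fit_mle(small_eeo_dataset, spec, grid, n_samples=200, seed=3)
    assert fit.params == eeo_params
    assert fit.log_likelihood == pytest.approx(
        vp.log_likelihood(small_eeo_dataset, spec, eeo_params, 200, seed=3))


def test_fit_rejects_empty_grid(small_eeo_dataset):
    spec = vp.parse_model_code("EEO")
    with pytest.raises(ValueError):
        vp.fit_mle(small_eeo_dataset, spec,
                   {"J_low": np.array([]), "J_high": np.array([5.0]),
                    "p_change": np.array([0.5])}, 100)


def test_fit_consistency_truth_beats_distant(eeo_params):
    spec = vp.parse_model_code("EEO")
    trials = vp.generate_trials(4000, np.random.default_rng(20))
    resp = vp.simulate_responses(trials, spec, eeo_params, seed=21)
    ll_true = vp.log_likelihood(resp, spec, eeo_params, 500, seed=22)
    distant = {"J_low": 80.0, "J_high": 90.0, "p_change": 0.7}
    ll_far = vp.log_likelihood(resp, spec, distant, 500, seed=22)
    assert ll_true > ll_far + 100


def test_fit_warns_when_criterion_pinned(small_eeo_dataset):
    spec = vp.parse_model_code("EEM")
    grid = {"J_low": np.array([4.5]), "J_high": np.array([11.6]),
            "k": np.array([40.0, 51.8])}
    with pytest.warns(UserWarning, match="boundary"):
        vp.fit_mle(small_eeo_dataset, spec, grid, n_samples=150, seed=4)


def test_grid_builders():
    spec = vp.parse_model_code("VSO")
    grid = vp.make_grid(spec, points_per_dim=8)
    assert grid["Jbar_low"].size == 8 and grid["J_assumed"].size == 8
    assert grid["p_change"].size == 29  # threshold axes use the nested ladder
    assert grid["p_change"][0] == 0.3 and grid["p_change"][-1] == 0.7
    cfg = {"J_low": {"min": 1, "max": 100, "points": 5},
           "J_high": {"min": 1, "max": 100, "points": 5},
           "p_change": {"min": 0.3, "max": 0.7, "points": 3}}
    grid = vp.grid_from_config(cfg, vp.parse_model_code("EEO"))
    assert np.allclose(grid["p_change"], [0.3, 0.5, 0.7])
    with pytest.raises(ValueError):
        vp.grid_from_config({"J_low": {"min": 1, "max": 9, "points": 2}},
                            vp.parse_model_code("EEO"))
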