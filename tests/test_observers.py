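"""The model taxonomy, local decision variables and integration rules."""
import numpy as np
import pytest

import vpchange as vp
from vpchange.encoding import log_i0, vm_pdf
from vpchange.observers import TrialPercept

EXPECTED_PARAM_COUNTS = {
    "VVO": 4, "VEO": 4, "VAO": 4, "VSO": 5, "VVM": 4, "VEM": 4, "VAM": 4,
    "VSM": 4, "EEO": 3, "EAO": 3, "ESO": 4, "EEM": 3, "EAM": 3, "ESM": 3,
}


def test_taxonomy_enumeration():
    models = vp.enumerate_models()
    assert len(models) == 14
    assert [m.code for m in models] == list(vp.MODEL_CODES)
    for m in models:
        assert len(m.free_params) == EXPECTED_PARAM_COUNTS[m.code]
        assert not (m.encoding == "E" and m.assumption == "V")
    assert max(len(m.free_params) for m in models) == 5


def test_model_code_parsing():
    assert vp.parse_model_code("EEO+local").free_params[-1] == "sigma_local"
    with pytest.raises(ValueError):
        vp.parse_model_code("XXO")
    with pytest.raises(ValueError):
        vp.parse_model_code("EVO")  # redundant under equal precision
    with pytest.raises(ValueError):
        vp.ModelSpec("V", "V", "O", noise="local")  # noise only for EEO


def test_validate_params():
    spec = vp.parse_model_code("EEO")
    with pytest.raises(ValueError):
        vp.validate_params(spec, {"J_low": 5, "J_high": 20})  # missing p_change
    with pytest.raises(ValueError):
        vp.validate_params(spec, {"J_low": -5, "J_high": 20, "p_change": 0.5})
    ok = vp.validate_params(spec, {"J_low": 5, "J_high": 20, "p_change": 0.5})
    assert set(ok) == {"J_low", "J_high", "p_change"}


def _oracle_d(xi, yi, kx, ky, n_grid=4096):
    """Likelihood ratio by numerical marginalization of the generative model.

    No change: x, y are measurements of one uniform theta. Change: the second
    orientation is offset by a uniform Delta; the double (theta, Delta)
    integral is evaluated by iterated trapezoid sums on the periodic grid.
    """
    th = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    p_no = np.mean(vm_pdf(xi, th, kx) * vm_pdf(yi, th, ky))
    inner = np.mean(vm_pdf(yi, th[:, None] + th[None, :], ky), axis=1)  # over Delta
    p_ch = np.mean(vm_pdf(xi, th, kx) * inner)
    return p_ch / p_no


def test_decision_variable_against_marginalization_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        kx, ky = rng.uniform(0.0, 80.0, 2)
        xi, yi = rng.uniform(-np.pi, np.pi, 2)
        d = vp.local_decision_variable(xi, yi, kx, ky)
        assert d == pytest.approx(_oracle_d(xi, yi, kx, ky), rel=1e-4)


def test_decision_variable_no_information():
    assert vp.local_decision_variable(1.0, -2.0, 0.0, 0.0) == pytest.approx(1.0)


def test_decision_variable_identical_measurements():
    for kappa in (2.0, 10.0, 40.0):
        d = vp.local_decision_variable(0.3, 0.3, kappa, kappa)
        expected = np.exp(2 * log_i0(kappa) - log_i0(2 * kappa))
        assert d == pytest.approx(expected, rel=1e-12)
        assert d <= 1.0
        assert d == pytest.approx(_oracle_d(0.3, 0.3, kappa, kappa), rel=1e-4)


def test_decision_variable_monotone_in_circular_distance():
    w = np.linspace(0, np.pi, 200)
    d = vp.local_decision_variable(w, np.zeros_like(w), 6.0, 14.0)
    assert np.all(np.diff(d) > 0)


def test_decision_variable_rejects_bad_input():
    with pytest.raises(ValueError):
        vp.local_decision_variable(np.nan, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        vp.local_decision_variable(0.0, 0.0, -1.0, 1.0)


def test_optimal_rule_boundary_and_cases():
    assert vp.optimal_rule([1.0, 1.0, 1.0, 1.0], 0.5) is False  # exact tie
    assert vp.optimal_rule([9.0, 1.0, 1.0, 1.0], 0.5) is True
    with pytest.raises(ValueError):
        vp.optimal_rule([1.0, -1.0, 1.0, 1.0], 0.5)
    with pytest.raises(ValueError):
        vp.optimal_rule([1.0] * 4, 1.5)


def test_optimal_rule_degenerate_priors():
    rng = np.random.default_rng(8)
    d = rng.uniform(0.01, 5.0, size=(50, 4))
    assert all(vp.optimal_rule(row, 1 - 1e-12) for row in d)
    assert not any(vp.optimal_rule(row, 1e-12) for row in d)


def test_optimal_rule_matches_bruteforce_posterior():
    """Decisions agree with a Bayes posterior computed by numerical
    marginalization of the full generative model (x, y | C)."""
    rng = np.random.default_rng(9)
    th = np.linspace(-np.pi, np.pi, 2048, endpoint=False)
    n_agree = 0
    n = 400
    for _ in range(n):
        kx = rng.uniform(0.5, 40.0, 4)
        ky = rng.uniform(0.5, 40.0, 4)
        x = rng.uniform(-np.pi, np.pi, 4)
        y = rng.uniform(-np.pi, np.pi, 4)
        p_change = rng.uniform(0.2, 0.8)
        p_no = np.array([np.mean(vm_pdf(x[i], th, kx[i]) * vm_pdf(y[i], th, ky[i]))
                         for i in range(4)])
        u_x = np.array([np.mean(vm_pdf(x[i], th, kx[i])) for i in range(4)])
        u_y = np.array([np.mean(vm_pdf(y[i], th, ky[i])) for i in range(4)])
        p_ch = u_x * u_y  # (theta, Delta) double integral factorizes
        lik_no = np.prod(p_no)
        lik_ch = np.mean([p_ch[i] * np.prod(np.delete(p_no, i)) for i in range(4)])
        posterior_change = (p_change * lik_ch
                            / (p_change * lik_ch + (1 - p_change) * lik_no))
        d = vp.local_decision_variable(x, y, kx, ky)
        n_agree += vp.optimal_rule(d, p_change) == (posterior_change > 0.5)
    assert n_agree == n


def test_max_rule():
    assert vp.max_rule([0.5, 0.9, 1.1, 0.7], 1.0) is True
    assert vp.max_rule([0.5, 0.9, 1.1, 0.7], 2.0) is False
    assert vp.max_rule([0.5, 0.9, 1.1, 0.7], 1.1) is False  # tie -> no change
    assert vp.max_rule([0.5, 0.9, 1.1, 0.7], -1.0) is True


def test_decision_noise_zero_sigma_matches_optimal():
    rng = np.random.default_rng(10)
    for _ in range(100):
        d = rng.uniform(0.05, 6.0, 4)
        p = rng.uniform(0.2, 0.8)
        for variant in ("local", "global"):
            assert vp.apply_decision_noise(d, variant, 0.0, p, rng) == \
                vp.optimal_rule(d, p)


def test_decision_noise_large_sigma_randomizes():
    rng = np.random.default_rng(11)
    reports = [vp.apply_decision_noise([0.01, 0.01, 0.01, 0.01], "global",
                                       1e4, 0.5, rng) for _ in range(2000)]
    assert 0.45 < np.mean(reports) < 0.55


def test_assumed_kappas():
    percept = TrialPercept(
        x=np.zeros(4), y=np.zeros(4),
        realized_jx=np.array([2.0, 4.0, 6.0, 8.0]),
        realized_jy=np.array([3.0, 5.0, 7.0, 9.0]),
        reliabilities=np.array([True, False, True, False]))
    # single assumed precision
    kx, ky = vp.assumed_kappas(percept, vp.parse_model_code("VSO"),
                               {"J_assumed": 15.0})
    assert np.allclose(kx, vp.kappa_from_j(15.0))
    assert np.allclose(ky, vp.kappa_from_j(15.0))
    # display-average assumed precision
    kx, ky = vp.assumed_kappas(percept, vp.parse_model_code("VAO"), {})
    assert np.allclose(kx, vp.kappa_from_j(5.0))
    assert np.allclose(ky, vp.kappa_from_j(6.0))
    # omniscient
    kx, _ = vp.assumed_kappas(percept, vp.parse_model_code("VVO"), {})
    assert np.allclose(kx, vp.kappa_from_j(percept.realized_jx))


def test_assumption_v_equals_e_under_equal_precision():
    """With equal-precision encoding there is no extra variability to know,
    so the omniscient and reliability-based assumptions coincide."""
    params = {"J_low": 6.0, "J_high": 18.0}
    rel = np.array([True, True, False, False])
    j = np.where(rel, params["J_high"], params["J_low"])
    percept = TrialPercept(x=np.zeros(4), y=np.zeros(4), realized_jx=j,
                           realized_jy=j.copy(), reliabilities=rel)
    spec_v = vp.ModelSpec("E", "V", "O")  # constructible, not canonical
    spec_e = vp.ModelSpec("E", "E", "O")
    assert not spec_v.is_canonical
    kv = vp.assumed_kappas(percept, spec_v, params)
    ke = vp.assumed_kappas(percept, spec_e, params)
    assert np.allclose(kv[0], ke[0]) and np.allclose(kv[1], ke[1])
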