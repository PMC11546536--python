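import numpy as np
import pytest
from scipy import stats

import hybridec as h
from hybridec.estimators import clever_covariate, dr_weights


def _fits_like(data, m1, m0, pi_d, pi_a=None, r=None):
    n = data.n
    return h.NuisanceFits(
        m1=np.asarray(m1, float),
        m0=np.asarray(m0, float),
        pi_d=np.asarray(pi_d, float),
        pi_a=np.full(n, 2 / 3) if pi_a is None else np.asarray(pi_a, float),
        r=np.ones(n) if r is None else np.asarray(r, float),
        fold_id=np.zeros(n, int),
        learner_spec=h.LearnerSpec(),
    )


# -- component estimators ----------------------------------------------------


def test_mu1_is_treated_arm_mean(micro_data):
    assert h.mu1_hat(micro_data) == pytest.approx(4.0)  # (3 + 5) / 2
    uneven = h.HybridTrialData(
        y=[1.0, 2.0, 6.0, 0.0], a=[1, 1, 1, 0], d=[1, 1, 1, 1], x=np.zeros((4, 1))
    )
    assert h.mu1_hat(uneven) == pytest.approx(3.0)


def test_mu1_requires_treated():
    data = h.HybridTrialData(y=[1.0, 2.0], a=[0, 0], d=[1, 1], x=np.zeros((2, 1)))
    with pytest.raises(h.EstimationError):
        h.mu1_hat(data)


def test_mu0_om_averages_over_study_only(micro_data):
    # m0-hat(x) = x1; study covariates are {0.5, 1.5, 0.0, 1.0} -> mean 0.75
    fits = _fits_like(micro_data, m1=np.zeros(6), m0=micro_data.x[:, 0], pi_d=np.full(6, 0.5))
    assert h.estimate_mu0_om(micro_data, fits) == pytest.approx(0.75)
    # constant model: mu0 = c regardless of covariates
    fits_c = _fits_like(micro_data, m1=np.zeros(6), m0=np.full(6, 3.3), pi_d=np.full(6, 0.5))
    assert h.estimate_mu0_om(micro_data, fits_c) == pytest.approx(3.3)
    # perturbing external-control covariate entries of m0-hat leaves it unchanged
    m0 = micro_data.x[:, 0].copy()
    m0[micro_data.d == 0] += 100.0
    fits_p = _fits_like(micro_data, m1=np.zeros(6), m0=m0, pi_d=np.full(6, 0.5))
    assert h.estimate_mu0_om(micro_data, fits_p) == pytest.approx(0.75)


def test_ipdw_weight_hand_values(micro_data):
    fits = _fits_like(
        micro_data,
        m1=np.zeros(6),
        m0=np.zeros(6),
        pi_d=np.full(6, 0.5),
        pi_a=np.full(6, 2 / 3),
    )
    w = h.ipdw_weights(micro_data, fits)
    assert np.all(w[micro_data.a == 1] == 0)
    # control with pi_d = 0.5, pi_a = 2/3: 0.5 / ((1/3)(0.5) + 0.5) = 0.75
    np.testing.assert_allclose(w[micro_data.a == 0], 0.75)
    # pi_d -> 1 recovers the classical within-trial weight 1 / (1 - pi_a)
    fits1 = _fits_like(micro_data, m1=np.zeros(6), m0=np.zeros(6), pi_d=np.ones(6))
    w1 = h.ipdw_weights(micro_data, fits1)
    np.testing.assert_allclose(w1[micro_data.a == 0], 3.0)


def test_mu0_ipdw_hand_case():
    data = h.HybridTrialData(
        y=[9.0, 4.0, 8.0], a=[1, 0, 0], d=[1, 1, 0], x=np.zeros((3, 1)), pi_a_design=0.5
    )
    # engineer pi_d so the control weights come out {0.75, 0.25}:
    # w = pi_d / (1 - pi_d / 2) with pi_a = 1/2, so pi_d = 6/11 and 2/9
    fits = _fits_like(data, m1=np.zeros(3), m0=np.zeros(3), pi_d=[0.5, 6 / 11, 2 / 9],
                      pi_a=np.full(3, 0.5))
    w = h.ipdw_weights(data, fits)
    np.testing.assert_allclose(w, [0.0, 0.75, 0.25])
    # unnormalized with n_rct = 1: (0.75*4 + 0.25*8) / 1 = 5 ... here n_rct = 2
    assert h.estimate_mu0_ipdw(data, fits) == pytest.approx(5.0 / 2)
    assert h.estimate_mu0_ipdw(data, fits, normalize=True) == pytest.approx(5.0)
    # weighted mean of a constant outcome is that constant
    const = h.HybridTrialData(
        y=[7.0, 7.0, 7.0], a=[1, 0, 0], d=[1, 1, 0], x=np.zeros((3, 1)), pi_a_design=0.5
    )
    assert h.estimate_mu0_ipdw(const, fits, normalize=True) == pytest.approx(7.0)


# -- efficient influence curve ----------------------------------------------


def test_eic_hand_values():
    # treated trial subject with y = m1 and m1 - m0 = tau: all residuals vanish
    assert h.eic_value(y=2.0, a=1, d=1, m1=2.0, m0=1.0, pi_a=2 / 3, pi_d=0.5,
                       r=1.0, tau=1.0, q=0.75) == pytest.approx(0.0)
    # internal control: W^dr = 0.5 / ((0.5)(1/3) + 0.5) = 0.75, phi = -(1/0.75)*0.75*1 = -1
    assert h.eic_value(y=1.0, a=0, d=1, m1=1.0, m0=0.0, pi_a=2 / 3, pi_d=0.5,
                       r=1.0, tau=1.0, q=0.75) == pytest.approx(-1.0)
    # external control with r = 1 and the same propensities: identical W^dr
    w_int = dr_weights(a=0, d=1, pi_a=2 / 3, pi_d=0.5, r=1.0)
    w_ext = dr_weights(a=0, d=0, pi_a=2 / 3, pi_d=0.5, r=1.0)
    assert w_int == pytest.approx(0.75)
    assert w_ext == pytest.approx(w_int)


def test_aipw_matches_brute_force_oracle(micro_data, micro_fits):
    """Independent spreadsheet-style evaluation of the six phi terms."""
    est = h.estimate_tau_aipw(micro_data, micro_fits)
    q = micro_data.n_rct / micro_data.n
    total = 0.0
    for i in range(micro_data.n):
        y, a, d = micro_data.y[i], micro_data.a[i], micro_data.d[i]
        m1, m0 = micro_fits.m1[i], micro_fits.m0[i]
        pa, pd_, r = micro_fits.pi_a[i], micro_fits.pi_d[i], micro_fits.r[i]
        num = d * (1 - a) * pd_ + (1 - d) * (1 - a) * pd_ * r
        den = pd_ * (1 - pa) + (1 - pd_) * r
        w = num / den
        total += (d * (m1 - m0) + d * a / pa * (y - m1) - w * (y - m0)) / q
    oracle = total / micro_data.n
    assert est.tau_hat == pytest.approx(oracle, rel=1e-12)
    # the estimating equation is solved exactly
    assert abs(np.mean(est.influence_values)) <= 1e-12


def test_aipw_exact_when_nuisances_true_and_noiseless():
    rng = np.random.default_rng(4)
    n = 40
    x = rng.standard_normal((n, 1))
    d = np.concatenate([np.ones(30, int), np.zeros(10, int)])
    a = np.where(d == 1, rng.integers(0, 2, n), 0)
    a[:2] = [1, 0]
    m0 = 1.0 + 2.0 * x[:, 0]
    m1 = m0 + 1.5
    y = np.where(a == 1, m1, m0)  # noiseless
    data = h.HybridTrialData(y=y, a=a, d=d, x=x, pi_a_design=0.5)
    fits = _fits_like(data, m1=m1, m0=m0, pi_d=np.full(n, 0.7), pi_a=np.full(n, 0.5))
    est = h.estimate_tau_aipw(data, fits)
    assert est.tau_hat == pytest.approx(1.5, rel=1e-12)


def test_aipw_reduces_to_trial_aipw_without_external_controls():
    rng = np.random.default_rng(8)
    n = 50
    x = rng.standard_normal((n, 1))
    a = rng.integers(0, 2, n)
    a[:2] = [0, 1]
    y = x[:, 0] + a + rng.standard_normal(n)
    data = h.HybridTrialData(y=y, a=a, d=np.ones(n, int), x=x, pi_a_design=0.5)
    m1 = x[:, 0] + 1
    m0 = x[:, 0]
    fits = _fits_like(data, m1=m1, m0=m0, pi_d=np.ones(n), pi_a=np.full(n, 0.5))
    est = h.estimate_tau_aipw(data, fits)
    # standard trial AIPW with weights A/pi_a and (1-A)/(1-pi_a)
    oracle = np.mean(
        m1 - m0 + a / 0.5 * (y - m1) - (1 - a) / 0.5 * (y - m0)
    )
    assert est.tau_hat == pytest.approx(oracle, rel=1e-12)


# -- confidence intervals ----------------------------------------------------


def test_closed_form_ci_hand_arithmetic():
    rng = np.random.default_rng(0)
    phi = rng.standard_normal(400)
    phi = (phi - phi.mean()) / phi.std(ddof=1) * 2.0  # var exactly 4
    lo, hi, se, p = h.closed_form_ci(phi, tau_hat=1.0, alpha=0.05)
    assert se == pytest.approx(0.1)
    assert (lo, hi) == (pytest.approx(0.804, abs=1e-3), pytest.approx(1.196, abs=1e-3))
    assert p == pytest.approx(2 * stats.norm.sf(10.0), rel=1e-6)
    # z-multiplier follows alpha
    lo32, hi32, _, _ = h.closed_form_ci(phi, tau_hat=1.0, alpha=0.32)
    assert (hi32 - lo32) / (hi - lo) == pytest.approx(
        stats.norm.ppf(0.84) / stats.norm.ppf(0.975), rel=1e-6
    )


def test_closed_form_ci_zero_variance():
    lo, hi, se, _ = h.closed_form_ci(np.zeros(10), tau_hat=2.0)
    assert (lo, hi, se) == (2.0, 2.0, 0.0)


# -- TMLE ---------------------------------------------------------------------


def test_tmle_zero_fluctuation_is_identity():
    """Noiseless data fit exactly: residuals vanish, epsilon = 0, and the
    targeted estimate equals the plug-in of the initial fits."""
    rng = np.random.default_rng(5)
    n = 60
    x = rng.standard_normal((n, 1))
    d = np.concatenate([np.ones(45, int), np.zeros(15, int)])
    a = np.where(d == 1, rng.integers(0, 2, n), 0)
    a[:2] = [1, 0]
    # pin the observed outcome range so every counterfactual prediction
    # lies inside [min Y, max Y] (otherwise the bounding clips it)
    i_max, i_min = int(np.argmax(x)), int(np.argmin(x))
    a[i_max], d[i_max] = 1, 1
    if i_min != i_max:
        a[i_min] = 0
    m0 = 1.0 + x[:, 0]
    m1 = m0 + 2.0
    y = np.where(a == 1, m1, m0)
    data = h.HybridTrialData(y=y, a=a, d=d, x=x, pi_a_design=0.5)
    fits = _fits_like(data, m1=m1, m0=m0, pi_d=np.full(n, 0.7), pi_a=np.full(n, 0.5))
    fl = h.tmle_fluctuate(data, fits)
    # identity up to the boundary clip applied before the logit transform
    assert fl.epsilon == pytest.approx(0.0, abs=1e-4)
    est = h.estimate_tau_tmle(data, fits)
    plug_in = np.mean(m1[d == 1] - m0[d == 1])
    assert est.tau_hat == pytest.approx(plug_in, abs=1e-4)


def test_tmle_solves_influence_equation(linear_data, linear_fits):
    est = h.estimate_tau_tmle(linear_data, linear_fits)
    assert abs(np.mean(est.influence_values)) <= 1e-6


def test_tmle_predictions_respect_outcome_range(linear_data, linear_fits):
    fl = h.tmle_fluctuate(linear_data, linear_fits)
    assert fl.m1_star.min() >= fl.lower and fl.m1_star.max() <= fl.upper
    assert fl.m0_star.min() >= fl.lower and fl.m0_star.max() <= fl.upper
    est = h.estimate_tau_tmle(linear_data, linear_fits)
    span = fl.upper - fl.lower
    assert -span <= est.tau_hat <= span


def test_tmle_close_to_aipw_on_well_specified_data(linear_data, linear_fits):
    a = h.estimate_tau_aipw(linear_data, linear_fits)
    t = h.estimate_tau_tmle(linear_data, linear_fits)
    assert t.tau_hat == pytest.approx(a.tau_hat, abs=0.05)


# -- RCT-only comparator ------------------------------------------------------


def test_rct_estimator_is_trial_subset_aipw(linear_data):
    est = h.estimate_tau_rct(linear_data, spec=h.LearnerSpec(), k_folds=1, seed=0)
    trial = linear_data.subset(linear_data.d == 1)
    fits = h.fit_nuisances(trial, spec=h.LearnerSpec(), k_folds=1, seed=0, study_only=True)
    np.testing.assert_array_equal(fits.pi_d, 1.0)
    oracle = h.estimate_tau_aipw(trial, fits)
    assert est.tau_hat == pytest.approx(oracle.tau_hat, rel=1e-12)
    assert est.method == "rct_aipw"


def test_rct_estimator_exact_in_noiseless_linear_truth():
    rng = np.random.default_rng(12)
    n = 30
    x = rng.standard_normal((n, 1))
    a = rng.integers(0, 2, n)
    a[:2] = [0, 1]
    y = 2.0 + x[:, 0] + 1.25 * a  # no noise, linear truth
    data = h.HybridTrialData(y=y, a=a, d=np.ones(n, int), x=x, pi_a_design=0.5)
    est = h.estimate_tau_rct(data, spec=h.LearnerSpec(), k_folds=1, seed=0)
    assert est.tau_hat == pytest.approx(1.25, rel=1e-10)


# -- bootstrap ----------------------------------------------------------------


def test_bootstrap_deterministic_given_seed(micro_data):
    a1 = h.bootstrap_ci(micro_data, "om", B=5, seed=3)
    a2 = h.bootstrap_ci(micro_data, "om", B=5, seed=3)
    assert a1[:3] == a2[:3]
    np.testing.assert_array_equal(a1[3], a2[3])


def test_bootstrap_degenerate_constant_outcome():
    data = h.HybridTrialData(
        y=np.full(8, 4.0),
        a=[1, 1, 0, 0, 0, 0, 0, 0],
        d=[1, 1, 1, 1, 1, 1, 0, 0],
        x=np.arange(8, dtype=float)[:, None],
        pi_a_design=0.5,
    )
    lo, hi, _, draws = h.bootstrap_ci(data, "om", B=10, seed=0)
    assert lo == pytest.approx(0.0, abs=1e-10) and hi == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(draws, 0.0, atol=1e-10)


# -- invariances --------------------------------------------------------------


def test_outcome_shift_invariance(linear_data):
    """Adding a constant to all outcomes shifts mu0-type quantities by that
    constant and leaves every tau estimate unchanged."""
    c = 17.5
    shifted = h.HybridTrialData(
        y=linear_data.y + c, a=linear_data.a, d=linear_data.d, x=linear_data.x,
        covariate_names=linear_data.covariate_names, pi_a_design=linear_data.pi_a_design,
    )
    spec = h.LearnerSpec()
    f0 = h.fit_nuisances(linear_data, spec=spec, k_folds=1, seed=5)
    f1 = h.fit_nuisances(shifted, spec=spec, k_folds=1, seed=5)
    assert h.estimate_mu0_om(shifted, f1) == pytest.approx(
        h.estimate_mu0_om(linear_data, f0) + c, rel=1e-10
    )
    for fn in (h.estimate_tau_aipw, h.estimate_tau_tmle):
        assert fn(shifted, f1).tau_hat == pytest.approx(fn(linear_data, f0).tau_hat, abs=1e-6)
    assert h.estimate_tau_om(shifted, f1).tau_hat == pytest.approx(
        h.estimate_tau_om(linear_data, f0).tau_hat, abs=1e-10
    )
    # the Hajek (normalized) IPDW form is exactly shift invariant; the
    # unnormalized form as defined is only invariant when the weights
    # average to one, so the invariance is asserted for the former
    assert h.estimate_tau_ipdw(shifted, f1, normalize=True).tau_hat == pytest.approx(
        h.estimate_tau_ipdw(linear_data, f0, normalize=True).tau_hat, abs=1e-10
    )
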