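"""Valuation model, likelihood, schedule builder, agent, and MLE recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from relapsekit import decision as d


# ---------------------------------------------------------------------------
# Prelec weighting and utility
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, gamma, expected",
    [
        (0.5, 1.0, 0.5),                       # gamma=1 is the identity
        (1 / math.e, 2.7, 1 / math.e),          # fixed point at 1/e for any gamma
        (0.1, 0.5, math.exp(-math.log(10) ** 0.5)),  # closed form ~0.21928
        (1.0, 0.3, 1.0),                        # certainty is never distorted
    ],
)
def test_prelec_values(p, gamma, expected):
    assert d.prelec_weight(p, gamma) == pytest.approx(expected, rel=1e-12)


@given(gamma=st.floats(0.1, 4.0))
@settings(max_examples=40, derandomize=True)
def test_prelec_identity_and_fixed_point(gamma):
    grid = np.linspace(0.01, 1.0, 50)
    w = d.prelec_weight(grid, gamma)
    assert np.all(np.diff(w) > 0)  # strictly increasing in p
    assert d.prelec_weight(1 / math.e, gamma) == pytest.approx(1 / math.e, rel=1e-12)
    assert np.all((w > 0) & (w <= 1))
    assert np.allclose(d.prelec_weight(grid, 1.0), grid)


@pytest.mark.parametrize("p", [0.0, -0.1, 1.0001])
def test_prelec_domain_errors(p):
    with pytest.raises(ValueError):
        d.prelec_weight(p, 1.0)
    with pytest.raises(ValueError):
        d.prelec_weight(0.5, 0.0)


@pytest.mark.parametrize(
    "x, lam, x_scale, expected",
    [
        (5000, 1.0, 5000, 1.0),
        (1250, 0.5, 5000, 0.5),
        (2500, 0.530, 5000, 0.5 ** 0.530),
    ],
)
def test_utility_values(x, lam, x_scale, expected):
    assert d.utility(x, lam, x_scale) == pytest.approx(expected, rel=1e-12)


def test_utility_domain_errors():
    with pytest.raises(ValueError):
        d.utility(-1.0, 1.0, 5000)
    with pytest.raises(ValueError):
        d.utility(100.0, 0.0, 5000)


def test_subjective_value_composition():
    # expected-value case, certain maximal reward, and a hand-computed point
    ev = d.subjective_value(d.GambleOption(0.5, 5000), d.RiskPreferenceParams(1, 1, 1), 5000)
    assert ev == pytest.approx(0.5)
    certain = d.subjective_value(
        d.GambleOption(1.0, 5000), d.RiskPreferenceParams(0.241, 0.7, 1), 5000
    )
    assert certain == pytest.approx(1.0)
    hand = math.exp(-((-math.log(0.3)) ** 0.5))
    got = d.subjective_value(
        d.GambleOption(0.3, 5000), d.RiskPreferenceParams(0.5, 0.5, 1), 5000
    )
    assert got == pytest.approx(hand, rel=1e-12)


def test_choice_probability_symmetry_and_logistic_point():
    opt = d.GambleOption(0.4, 3000)
    trial = d.GambleTrial(opt, opt)
    for params in (d.RiskPreferenceParams(1, 1, 5), d.RiskPreferenceParams(0.3, 2, 50)):
        assert d.choice_probability(trial, params, 5000) == pytest.approx(0.5)
    # SV_A - SV_B = 0.2 at tau 5 -> logistic(1)
    t2 = d.GambleTrial(d.GambleOption(0.7, 5000), d.GambleOption(0.5, 5000))
    p = d.choice_probability(t2, d.RiskPreferenceParams(1, 1, 5), 5000)
    assert p == pytest.approx(1 / (1 + math.exp(-1)), rel=1e-12)
    # saturation
    t3 = d.GambleTrial(d.GambleOption(0.9, 5000), d.GambleOption(0.1, 5000))
    assert d.choice_probability(t3, d.RiskPreferenceParams(1, 1, 1e4), 5000) > 0.9999


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_nll_single_even_trial():
    opt = d.GambleOption(0.5, 5000)
    trial = d.GambleTrial(opt, opt, choice="A", response_time=1.0)
    nll = d.negative_log_likelihood([trial], d.RiskPreferenceParams(1, 1, 3), 5000)
    assert nll == pytest.approx(math.log(2), rel=1e-12)


def test_nll_matches_brute_force_per_trial_sum(schedule):
    params = d.RiskPreferenceParams(0.6, 1.3, 8.0)
    trials = d.simulate_agent(schedule, params, seed=5)
    x_scale = schedule.x_scale
    fitted = d.negative_log_likelihood(trials, params, x_scale)
    brute = 0.0
    for t in d.usable_trials(trials):
        p_a = d.choice_probability(t, params, x_scale)
        brute += -math.log(p_a if t.choice == "A" else 1 - p_a)
    assert fitted == pytest.approx(brute, abs=1e-10)


def test_nll_excludes_catch_and_no_response(schedule):
    params = d.RiskPreferenceParams(1, 1, 5)
    trials = d.simulate_agent(schedule, params, seed=6)
    base = d.negative_log_likelihood(trials, params, schedule.x_scale)
    # blanking all catch trials and adding a no-response trial changes nothing
    for t in trials:
        if t.is_catch:
            t.choice = "none"
    extra = d.GambleTrial(d.GambleOption(0.5, 1000), d.GambleOption(0.6, 900))
    assert d.negative_log_likelihood(trials + [extra], params, schedule.x_scale) == \
        pytest.approx(base, abs=1e-12)


def test_nll_near_zero_for_deterministic_agent(schedule):
    # curvature params avoid exact subjective-value ties on the option grid
    params = d.RiskPreferenceParams(0.83, 1.17, 1e6)
    trials = d.simulate_agent(schedule, params, seed=7)
    assert d.negative_log_likelihood(trials, params, schedule.x_scale) < 0.2


def test_nll_errors_without_usable_trials():
    opt = d.GambleOption(0.5, 5000)
    with pytest.raises(ValueError):
        d.negative_log_likelihood(
            [d.GambleTrial(opt, opt)], d.RiskPreferenceParams(1, 1, 1), 5000
        )


# ---------------------------------------------------------------------------
# schedule builder
# ---------------------------------------------------------------------------

def test_schedule_structure(schedule):
    assert len(schedule.trials) == 128
    assert sum(t.is_catch for t in schedule.trials) == 8
    assert sum(not t.is_catch for t in schedule.trials) == 120
    assert {t.session_index for t in schedule.trials} == {1, 2, 3}
    # one catch inside every block of 15 main trials
    main_seen = 0
    catches_per_block = [0] * 8
    for t in schedule.trials:
        if t.is_catch:
            # a catch follows a trial of its block, so >= 1 main trial precedes it
            catches_per_block[(main_seen - 1) // 15] += 1
        else:
            main_seen += 1
    assert catches_per_block == [1] * 8


def test_schedule_main_trials_non_dominated(schedule):
    for t in schedule.trials:
        if t.is_catch:
            assert d.dominant_option(t) in ("A", "B")
            assert t.option_a.magnitude == t.option_b.magnitude
            assert t.option_a.probability != t.option_b.probability
        else:
            assert d.dominant_option(t) is None


def test_schedule_deterministic_under_seed():
    a = d.build_task_schedule(seed=9)
    b = d.build_task_schedule(seed=9)
    assert a.trials == b.trials
    c = d.build_task_schedule(seed=10)
    assert a.trials != c.trials


def test_dominance_checker_catch_example():
    # the printed attention-check example: (30%, 5000) vs (50%, 5000)
    trial = d.GambleTrial(d.GambleOption(0.3, 5000), d.GambleOption(0.5, 5000), is_catch=True)
    assert d.dominant_option(trial) == "B"
    tie = d.GambleTrial(d.GambleOption(0.3, 5000), d.GambleOption(0.3, 5000))
    assert d.dominant_option(tie) is None


def test_schedule_config_rejects_tiny_grids():
    with pytest.raises(ValueError):
        d.ScheduleConfig(probabilities=(0.5,), magnitudes=(1000.0, 2000.0))


# ---------------------------------------------------------------------------
# agent simulation
# ---------------------------------------------------------------------------

def test_agent_reproducible_and_catch_correct(schedule):
    params = d.RiskPreferenceParams(0.8, 1.0, 10.0)
    a = d.simulate_agent(schedule, params, seed=3, lapse_rate=0.0)
    b = d.simulate_agent(schedule, params, seed=3, lapse_rate=0.0)
    assert a == b
    for t in a:
        if t.is_catch:
            assert t.choice == d.dominant_option(t)


def test_agent_matches_analytic_choice_probability():
    trial = d.GambleTrial(d.GambleOption(0.7, 3000), d.GambleOption(0.3, 9000))
    sched = d.TaskSchedule(trials=[trial], n_main_trials=1, n_catch=0)
    params = d.RiskPreferenceParams(0.7, 1.2, 8.0)
    p_analytic = d.choice_probability(trial, params, 9000.0)
    rng_seeds = range(10_000)
    chose_a = 0
    # resimulate the same single-trial schedule many times
    for s in rng_seeds:
        out = d.simulate_agent(sched, params, seed=s)
        chose_a += out[0].choice == "A"
    assert chose_a / 10_000 == pytest.approx(p_analytic, abs=0.02)


def test_agent_maximizes_ev_at_neutral_params(schedule):
    params = d.RiskPreferenceParams(1.0, 1.0, 1e5)
    trials = d.simulate_agent(schedule, params, seed=4)
    for t in trials:
        if t.is_catch:
            continue
        ev_a = t.option_a.probability * t.option_a.magnitude
        ev_b = t.option_b.probability * t.option_b.magnitude
        if abs(ev_a - ev_b) > 1e-9:
            assert t.choice == ("A" if ev_a > ev_b else "B")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_recovers_neutral_agent():
    """Median recovery across a few 120-trial risk-neutral agents."""
    lams, gams = [], []
    for i in range(5):
        sch = d.build_task_schedule(seed=50 + i)
        trials = d.simulate_agent(sch, d.RiskPreferenceParams(1.0, 1.0, 10.0), seed=60 + i)
        fit = d.fit_mle(trials, d.FitConfig(seed=i))
        assert fit.converged
        lams.append(fit.params.lambda_utility)
        gams.append(fit.params.gamma_weighting)
    assert 0.8 <= float(np.median(lams)) <= 1.2
    assert 0.8 <= float(np.median(gams)) <= 1.2


def test_fit_invariant_to_trial_order(schedule):
    trials = d.simulate_agent(schedule, d.RiskPreferenceParams(0.5, 1.0, 10.0), seed=8)
    fit1 = d.fit_mle(trials, d.FitConfig(seed=1))
    rng = np.random.default_rng(0)
    perm = list(trials)
    rng.shuffle(perm)
    fit2 = d.fit_mle(perm, d.FitConfig(seed=1))
    assert fit1.neg_log_likelihood == pytest.approx(fit2.neg_log_likelihood, abs=1e-8)
    assert fit1.params.lambda_utility == pytest.approx(fit2.params.lambda_utility, abs=1e-5)
    assert fit1.params.gamma_weighting == pytest.approx(fit2.params.gamma_weighting, abs=1e-5)


def test_fit_consistency_trial_ladder():
    """Median |lambda error| shrinks as trials grow 120 -> 1,200 -> 12,000."""
    true = d.RiskPreferenceParams(0.5, 1.0, 10.0)
    errors = []
    for n_blocks in (1, 10, 100):
        errs = []
        for i in range(3):
            parts = []
            for b in range(n_blocks):
                sch = d.build_task_schedule(seed=200 + 37 * i + b)
                parts += d.simulate_agent(sch, true, seed=300 + 41 * i + b)
            fit = d.fit_mle(parts, d.FitConfig(seed=i, n_starts=6))
            errs.append(abs(fit.params.lambda_utility - true.lambda_utility))
        errors.append(float(np.median(errs)))
    assert errors[0] > errors[1] > errors[2]


def test_fit_flags_degenerate_response_bias(schedule):
    trials = []
    for t in schedule.trials:
        t2 = d.GambleTrial(t.option_a, t.option_b, t.is_catch, t.session_index,
                           choice="A", response_time=1.0)
        trials.append(t2)
    fit = d.fit_mle(trials, d.FitConfig(seed=0, n_starts=8))
    assert fit.at_bound or not fit.converged


def test_fit_requires_minimum_trials(schedule):
    trials = d.simulate_agent(schedule, d.RiskPreferenceParams(1, 1, 5), seed=1)[:20]
    with pytest.raises(ValueError):
        d.fit_mle(trials, d.FitConfig(min_usable_trials=30))


def test_catch_accuracy_qc(schedule):
    trials = d.simulate_agent(schedule, d.RiskPreferenceParams(1, 1, 5), seed=2,
                              lapse_rate=0.0)
    assert d.catch_accuracy(trials) == 1.0
    # break two catches
    broken = 0
    for t in trials:
        if t.is_catch and broken < 2:
            t.choice = "B" if d.dominant_option(t) == "A" else "A"
            broken += 1
    assert d.catch_accuracy(trials) == pytest.approx(6 / 8)


def test_trials_roundtrip_through_frame(schedule):
    trials = d.simulate_agent(schedule, d.RiskPreferenceParams(0.7, 0.9, 12.0), seed=13,
                              no_response_rate=0.05)
    df = d.trials_to_frame(trials, "S001")
    back = d.frame_to_trials(df)
    assert back == trials
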