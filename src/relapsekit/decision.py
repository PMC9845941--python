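"""Risk-based decision-making task: valuation model, agent simulation, MLE fitting.

The task presents two-option gambles, each offering a reward magnitude ``x``
(JPY) with probability ``p``.  Options are valued by

    SV(p, x) = w(p; gamma) * u(x; lambda)

with the one-parameter Prelec probability weight ``w(p) = exp(-(-ln p)**gamma)``
and a power utility ``u(x) = (x / x_scale)**lambda``.  ``lambda`` is the
utility-sensitivity (risk-preference) parameter: 1 is risk-neutral, below 1
risk-averse, above 1 risk-seeking.  ``gamma`` distorts probabilities around the
fixed point 1/e: below 1 overweights small and underweights large
probabilities.  Choices follow a logistic (softmax) rule with inverse
temperature ``tau``; ``tau`` is a nuisance parameter estimated jointly but
never interpreted.

Per-subject parameters are recovered by bounded multi-start maximum-likelihood
estimation over the non-catch, responded trials.  Catch trials (one option
dominates: equal magnitude, strictly higher probability) probe attention and
are scored as a quality-control accuracy, never entered into the likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "GambleOption",
    "GambleTrial",
    "TaskSchedule",
    "RiskPreferenceParams",
    "RiskModelFit",
    "ScheduleConfig",
    "FitConfig",
    "prelec_weight",
    "utility",
    "subjective_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_mle",
    "build_task_schedule",
    "simulate_agent",
    "dominant_option",
    "usable_trials",
    "catch_accuracy",
    "trials_to_frame",
    "frame_to_trials",
    "fit_to_row",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GambleOption:
    """One side of a two-option gamble: win ``magnitude`` JPY with ``probability``."""

    probability: float
    magnitude: float

    def __post_init__(self) -> None:
        if not (0.0 < self.probability <= 1.0):
            raise ValueError(f"probability must be in (0, 1], got {self.probability}")
        if not self.magnitude > 0:
            raise ValueError(f"magnitude must be > 0, got {self.magnitude}")


@dataclass
class GambleTrial:
    """A single two-option risky choice; ``choice`` is 'A', 'B', or 'none'."""

    option_a: GambleOption
    option_b: GambleOption
    is_catch: bool = False
    session_index: int = 1
    choice: str = "none"
    response_time: float | None = None

    def __post_init__(self) -> None:
        if self.choice not in ("A", "B", "none"):
            raise ValueError(f"choice must be 'A', 'B' or 'none', got {self.choice!r}")


@dataclass
class TaskSchedule:
    """Ordered trial list: 120 main trials over 3 sessions plus 8 catch trials."""

    trials: list[GambleTrial]
    n_sessions: int = 3
    n_main_trials: int = 120
    n_catch: int = 8

    @property
    def x_scale(self) -> float:
        return max(max(t.option_a.magnitude, t.option_b.magnitude) for t in self.trials)

    def validate(self) -> None:
        n_main = sum(not t.is_catch for t in self.trials)
        n_catch = sum(t.is_catch for t in self.trials)
        if n_main != self.n_main_trials:
            raise ValueError(f"expected {self.n_main_trials} main trials, got {n_main}")
        if n_catch != self.n_catch:
            raise ValueError(f"expected {self.n_catch} catch trials, got {n_catch}")
        for t in self.trials:
            if t.is_catch and dominant_option(t) is None:
                raise ValueError("catch trial without a dominant option")


@dataclass(frozen=True)
class RiskPreferenceParams:
    """(lambda, gamma, tau): utility sensitivity, probability weighting, inverse temperature."""

    lambda_utility: float
    gamma_weighting: float
    tau_inverse_temperature: float

    def __post_init__(self) -> None:
        for name in ("lambda_utility", "gamma_weighting", "tau_inverse_temperature"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass
class RiskModelFit:
    params: RiskPreferenceParams
    neg_log_likelihood: float
    n_trials_used: int
    converged: bool
    n_starts: int
    best_start_index: int
    at_bound: bool = False
    catch_accuracy: float | None = None


@dataclass(frozen=True)
class ScheduleConfig:
    """Option grids and trial counts for the schedule builder.

    The option set is not fixed by the task description beyond the example
    catch pair; defaults span probabilities 0.1..0.9 and 500..10,000 JPY, and
    dominated main-trial pairs are rejected so every main trial trades
    probability against magnitude.
    """

    probabilities: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))
    magnitudes: tuple[float, ...] = tuple(float(m) for m in range(500, 10_500, 500))
    n_main_trials: int = 120
    n_sessions: int = 3
    catch_every: int = 15  # one catch after a random trial in each block of 15

    def __post_init__(self) -> None:
        if len(set(self.probabilities)) < 2 or len(set(self.magnitudes)) < 2:
            raise ValueError("need at least two distinct probabilities and magnitudes "
                             "to build non-dominated pairs")


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 20
    seed: int = 0
    min_usable_trials: int = 30
    lambda_bounds: tuple[float, float] = (0.05, 5.0)
    gamma_bounds: tuple[float, float] = (0.05, 5.0)
    tau_bounds: tuple[float, float] = (0.01, 100.0)
    catch_pass_threshold: float = 6 / 8  # QC: flag subjects below this catch accuracy


# ---------------------------------------------------------------------------
# valuation model
# ---------------------------------------------------------------------------

def prelec_weight(p, gamma):
    """Prelec probability weight ``w(p) = exp(-(-ln p)**gamma)``.

    Identity at gamma=1; fixed point w(1/e)=1/e for every gamma; strictly
    increasing in p with w(1)=1.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must be in (0, 1]")
    if not np.all(np.asarray(gamma) > 0):
        raise ValueError("gamma must be > 0")
    with np.errstate(divide="ignore"):
        out = np.exp(-((-np.log(p)) ** gamma))
    return out if out.ndim else float(out)


def utility(x, lam, x_scale):
    """Power utility ``u(x) = (x / x_scale)**lam`` on strictly positive magnitudes."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x must be > 0")
    if not (np.all(np.asarray(lam) > 0) and x_scale > 0):
        raise ValueError("lam and x_scale must be > 0")
    out = (x / x_scale) ** lam
    return out if out.ndim else float(out)


def subjective_value(option: GambleOption, params: RiskPreferenceParams, x_scale: float) -> float:
    """SV = w(p; gamma) * u(x; lambda); equals p*x/x_scale at lambda=gamma=1."""
    return float(
        prelec_weight(option.probability, params.gamma_weighting)
        * utility(option.magnitude, params.lambda_utility, x_scale)
    )


def choice_probability(trial: GambleTrial, params: RiskPreferenceParams, x_scale: float) -> float:
    """Probability of choosing option A: logistic in tau * (SV_A - SV_B)."""
    sv_a = subjective_value(trial.option_a, params, x_scale)
    sv_b = subjective_value(trial.option_b, params, x_scale)
    return float(expit(params.tau_inverse_temperature * (sv_a - sv_b)))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def usable_trials(trials: list[GambleTrial]) -> list[GambleTrial]:
    """Trials entering the likelihood: non-catch with a recorded response."""
    return [t for t in trials if not t.is_catch and t.choice != "none"]


def _pack_arrays(trials: list[GambleTrial]):
    """Vectorize usable trials into (p_a, x_a, p_b, x_b, chose_a) arrays."""
    use = usable_trials(trials)
    if not use:
        raise ValueError("no usable trials (non-catch with a response)")
    p_a = np.array([t.option_a.probability for t in use])
    x_a = np.array([t.option_a.magnitude for t in use])
    p_b = np.array([t.option_b.probability for t in use])
    x_b = np.array([t.option_b.magnitude for t in use])
    chose_a = np.array([t.choice == "A" for t in use])
    return p_a, x_a, p_b, x_b, chose_a


def _nll_core(lam, gam, tau, p_a, x_a, p_b, x_b, chose_a, x_scale):
    sv_a = np.exp(-((-np.log(p_a)) ** gam)) * (x_a / x_scale) ** lam
    sv_b = np.exp(-((-np.log(p_b)) ** gam)) * (x_b / x_scale) ** lam
    d = tau * (sv_a - sv_b)
    # log P(observed) = -log(1 + exp(-signed d)); numerically stable via logaddexp
    signed = np.where(chose_a, d, -d)
    return float(np.sum(np.logaddexp(0.0, -signed)))


def negative_log_likelihood(
    trials: list[GambleTrial], params: RiskPreferenceParams, x_scale: float
) -> float:
    """-sum log P(observed choice) over usable trials, in nats."""
    arrays = _pack_arrays(trials)
    nll = _nll_core(
        params.lambda_utility,
        params.gamma_weighting,
        params.tau_inverse_temperature,
        *arrays,
        x_scale,
    )
    if not np.isfinite(nll):
        raise FloatingPointError("non-finite likelihood")
    return nll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_mle(
    trials: list[GambleTrial],
    config: FitConfig | None = None,
    x_scale: float | None = None,
) -> RiskModelFit:
    """Multi-start bounded MLE of (lambda, gamma, tau).

    Optimizes in log-parameter space with L-BFGS-B from ``n_starts`` points
    drawn log-uniformly within the bounds (the first start is the
    risk-neutral/rational point lambda=gamma=1, tau=1).  Returns the best
    local optimum; ``converged`` reflects the winning start's optimizer
    status, ``at_bound`` flags estimates pinned at a box edge (e.g. a
    non-identifiable, response-bias agent drives tau to its bound).
    """
    config = config or FitConfig()
    if x_scale is None:
        x_scale = max(max(t.option_a.magnitude, t.option_b.magnitude) for t in trials)

    use = usable_trials(trials)
    if len(use) < config.min_usable_trials:
        raise ValueError(
            f"only {len(use)} usable trials; need at least {config.min_usable_trials}"
        )
    arrays = _pack_arrays(trials)

    lo = np.log([config.lambda_bounds[0], config.gamma_bounds[0], config.tau_bounds[0]])
    hi = np.log([config.lambda_bounds[1], config.gamma_bounds[1], config.tau_bounds[1]])

    def objective(theta_log):
        lam, gam, tau = np.exp(theta_log)
        return _nll_core(lam, gam, tau, *arrays, x_scale)

    rng = np.random.default_rng(config.seed)
    starts = [np.zeros(3)]  # lambda = gamma = tau = 1
    starts += [rng.uniform(lo, hi) for _ in range(max(config.n_starts - 1, 0))]
    starts = [np.clip(s, lo, hi) for s in starts]

    best = None
    best_idx = -1
    for i, s in enumerate(starts):
        res = minimize(objective, s, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if best is None or res.fun < best.fun:
            best, best_idx = res, i

    theta = np.clip(best.x, lo, hi)
    lam, gam, tau = np.exp(theta)
    at_bound = bool(np.any(theta - lo < 1e-6) or np.any(hi - theta < 1e-6))
    acc = catch_accuracy(trials)
    return RiskModelFit(
        params=RiskPreferenceParams(lam, gam, tau),
        neg_log_likelihood=float(best.fun),
        n_trials_used=len(use),
        converged=bool(best.success),
        n_starts=len(starts),
        best_start_index=best_idx,
        at_bound=at_bound,
        catch_accuracy=acc,
    )


def catch_accuracy(trials: list[GambleTrial]) -> float | None:
    """Fraction of catch trials answered with the dominant option (none = wrong)."""
    catches = [t for t in trials if t.is_catch]
    if not catches:
        return None
    correct = sum(t.choice == dominant_option(t) for t in catches)
    return correct / len(catches)


# ---------------------------------------------------------------------------
# schedule and agent
# ---------------------------------------------------------------------------

def dominant_option(trial: GambleTrial) -> str | None:
    """'A'/'B' if one option weakly dominates the other (strictly in one attribute)."""
    a, b = trial.option_a, trial.option_b
    if a.probability >= b.probability and a.magnitude >= b.magnitude and (
        a.probability > b.probability or a.magnitude > b.magnitude
    ):
        return "A"
    if b.probability >= a.probability and b.magnitude >= a.magnitude and (
        b.probability > a.probability or b.magnitude > a.magnitude
    ):
        return "B"
    return None


def build_task_schedule(config: ScheduleConfig | None = None, seed: int = 0) -> TaskSchedule:
    """Build the 120-main-trial / 3-session schedule with one catch per 15-trial block.

    Main trials pair options so neither dominates (one has the higher
    probability, the other the larger magnitude).  Catch trials hold magnitude
    fixed and vary probability, so the dominant option is unambiguous.
    """
    config = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    probs = np.array(sorted(config.probabilities), dtype=float)
    mags = np.array(sorted(config.magnitudes), dtype=float)

    per_session = config.n_main_trials // config.n_sessions

    main: list[GambleTrial] = []
    for i in range(config.n_main_trials):
        for _ in range(10_000):
            p = rng.choice(probs, size=2, replace=False)
            x = rng.choice(mags, size=2, replace=False)
            # anti-correlate: higher probability goes with the smaller magnitude
            order = np.argsort(p)
            p_lo, p_hi = p[order]
            x_pair = np.sort(x)[::-1]  # larger magnitude with lower probability
            opt_a = GambleOption(float(p_lo), float(x_pair[0]))
            opt_b = GambleOption(float(p_hi), float(x_pair[1]))
            if rng.random() < 0.5:
                opt_a, opt_b = opt_b, opt_a
            trial = GambleTrial(opt_a, opt_b, session_index=1 + i // per_session)
            if dominant_option(trial) is None:
                main.append(trial)
                break
        else:  # pragma: no cover - grids in config validation prevent this
            raise ValueError("option grids too small to build non-dominated pairs")

    n_blocks = config.n_main_trials // config.catch_every
    trials: list[GambleTrial] = []
    for b in range(n_blocks):
        block = main[b * config.catch_every : (b + 1) * config.catch_every]
        pos = int(rng.integers(config.catch_every))  # catch goes after this trial
        x = float(rng.choice(mags))
        p_pair = rng.choice(probs, size=2, replace=False)
        p_lo, p_hi = float(np.min(p_pair)), float(np.max(p_pair))
        if rng.random() < 0.5:
            catch = GambleTrial(GambleOption(p_lo, x), GambleOption(p_hi, x), is_catch=True)
        else:
            catch = GambleTrial(GambleOption(p_hi, x), GambleOption(p_lo, x), is_catch=True)
        catch.session_index = block[pos].session_index
        trials.extend(block[: pos + 1])
        trials.append(catch)
        trials.extend(block[pos + 1 :])

    schedule = TaskSchedule(
        trials=trials,
        n_sessions=config.n_sessions,
        n_main_trials=config.n_main_trials,
        n_catch=n_blocks,
    )
    schedule.validate()
    return schedule


def simulate_agent(
    schedule: TaskSchedule,
    params: RiskPreferenceParams,
    seed: int = 0,
    lapse_rate: float = 0.02,
    no_response_rate: float = 0.0,
) -> list[GambleTrial]:
    """Generate choices from the logistic valuation model.

    Main-trial choices are Bernoulli draws from ``choice_probability``; catch
    trials are answered with the dominant option except for ``lapse_rate``
    lapses.  Response times are drawn lognormal within the 3 s decision phase
    (descriptive only; the model makes no RT predictions).
    """
    rng = np.random.default_rng(seed)
    x_scale = schedule.x_scale
    out: list[GambleTrial] = []
    for t in schedule.trials:
        trial = replace(t)
        if no_response_rate > 0 and rng.random() < no_response_rate:
            trial.choice = "none"
            trial.response_time = None
            out.append(trial)
            continue
        if t.is_catch:
            best = dominant_option(t)
            other = "B" if best == "A" else "A"
            trial.choice = other if rng.random() < lapse_rate else best
        else:
            p_a = choice_probability(t, params, x_scale)
            trial.choice = "A" if rng.random() < p_a else "B"
        trial.response_time = float(np.clip(rng.lognormal(math.log(1.2), 0.35), 0.2, 3.0))
        out.append(trial)
    return out


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def trials_to_frame(trials: list[GambleTrial], subject_id: str) -> pd.DataFrame:
    rows = []
    for i, t in enumerate(trials):
        rows.append(
            dict(
                subject_id=subject_id,
                session=t.session_index,
                trial_index=i,
                p_a=t.option_a.probability,
                x_a=t.option_a.magnitude,
                p_b=t.option_b.probability,
                x_b=t.option_b.magnitude,
                is_catch=t.is_catch,
                choice=t.choice,
                rt_s=t.response_time if t.response_time is not None else np.nan,
            )
        )
    return pd.DataFrame(rows)


def frame_to_trials(df: pd.DataFrame) -> list[GambleTrial]:
    trials = []
    for row in df.itertuples(index=False):
        rt = None if pd.isna(row.rt_s) else float(row.rt_s)
        trials.append(
            GambleTrial(
                GambleOption(float(row.p_a), float(row.x_a)),
                GambleOption(float(row.p_b), float(row.x_b)),
                is_catch=bool(row.is_catch),
                session_index=int(row.session),
                choice=str(row.choice),
                response_time=rt,
            )
        )
    return trials


def fit_to_row(fit: RiskModelFit, subject_id: str) -> dict:
    return dict(
        subject_id=subject_id,
        **{
            "lambda": fit.params.lambda_utility,
            "gamma": fit.params.gamma_weighting,
            "tau": fit.params.tau_inverse_temperature,
        },
        nll=fit.neg_log_likelihood,
        n_trials_used=fit.n_trials_used,
        converged=fit.converged,
        at_bound=fit.at_bound,
        catch_accuracy=fit.catch_accuracy if fit.catch_accuracy is not None else np.nan,
    )
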