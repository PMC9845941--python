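"""Synthetic-cohort generator for the relapse-prediction pipeline.

Emulates a longitudinal inpatient cohort (default 24 abstainers, 17 relapsers)
with the statistical structure the downstream analysis assumes:

* covariates drawn normal (mean +/- SD variables) or lognormal matched to the
  reported median and quartile ratio (skewed variables), with sex assigned as
  exact per-group counts (21/3 and 14/3);
* per-subject risk-preference truths (lambda, gamma, tau) — lambda group
  medians 0.530 (relapsers) vs 0.241 (abstainers), gamma centered at 1 with no
  group difference, tau a lognormal nuisance;
* 120-main-trial gamble-choice logs simulated from the logistic valuation
  model;
* go/no-go, n-back, and VFT logs with group reaction-time and error-rate
  calibration (non-emotional RT shorter in relapsers; everything else null);
* multichannel fNIRS recordings: boxcar block designs convolved with a
  canonical double-gamma HRF, per-region amplitudes chosen so the processed
  emotional-minus-neutral contrast matches the configured group truth (right
  frontotemporal contrast lower in relapsers), plus 1/f noise, a cardiac
  sinusoid near 1.1 Hz, motion spikes, and channel gain heterogeneity.

Ground-truth latents live in a separate table from the "observed" outputs so
parameter-recovery tests cannot leak.  Everything is deterministic under
(config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gamma as gamma_dist

from . import decision, fnirs

__all__ = [
    "FnirsDesign",
    "FnirsNoise",
    "CohortConfig",
    "SyntheticDataset",
    "default_config",
    "lognormal_from_quartiles",
    "generate_cohort",
    "generate_risk_params",
    "generate_fnirs_recording",
    "generate_behavior_logs",
    "generate_choices",
    "generate_dataset",
    "write_dataset",
]

_Z75 = 0.6744897501960817  # standard-normal 75th percentile


def lognormal_from_quartiles(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matched to the median and quartile ratio.

    The median is matched exactly; sigma comes from ln(q75/q25) / (2 z_0.75).
    Printed IQRs are generally not log-symmetric, so individual quartiles are
    matched only in ratio — the two-parameter family cannot do better.
    """
    if not (0 < q25 <= median <= q75) or q25 == q75:
        raise ValueError(f"infeasible quartiles: median={median}, IQR=({q25}, {q75})")
    return math.log(median), math.log(q75 / q25) / (2 * _Z75)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FnirsDesign:
    """Block schedule and HRF shape for synthetic recordings.

    Go/no-go block length = 32 trials x 1.5 s; rest lengths are a design
    choice (the source task timing prints only the VFT periods, which are used
    verbatim: 30 s pre, 3 x 20 s production, 70 s post).
    """

    dt: float = 0.1
    gonogo_block_s: float = 48.0
    gonogo_rest_s: float = 30.0
    gonogo_order: tuple[str, ...] = (
        "control", "emotional", "control", "nonemotional", "control"
    )
    vft_pre_s: float = 30.0
    vft_production_s: float = 60.0
    vft_post_s: float = 70.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 6.0


@dataclass(frozen=True)
class FnirsNoise:
    """Additive noise amplitudes (concentration units, mM·mm)."""

    pink_sd: float = 0.3
    white_sd: float = 0.05
    cardiac_amp: float = 0.15
    cardiac_freq_mean: float = 1.1
    cardiac_freq_sd: float = 0.05
    spike_rate_per_min: float = 0.3
    spike_amp: float = 3.0
    channel_gain_sd: float = 0.15

    def silent(self) -> "FnirsNoise":
        return FnirsNoise(0.0, 0.0, 0.0, self.cardiac_freq_mean, 0.0, 0.0, 0.0, 0.0)


def _default_covariates() -> dict:
    """Per-group covariate distributions (normal: mean, sd; lognormal: median, q25, q75)."""
    return {
        "age": dict(kind="normal", abstainer=(55.0, 8.7), relapser=(51.6, 9.3)),
        "age_first_drink": dict(kind="lognormal", abstainer=(20.0, 18.0, 20.3),
                                relapser=(18.0, 16.0, 20.0)),
        "age_onset": dict(kind="lognormal", abstainer=(47.0, 34.8, 56.5),
                          relapser=(40.0, 35.0, 50.0)),
        "duration_illness": dict(kind="lognormal", abstainer=(7.5, 2.8, 13.3),
                                 relapser=(6.0, 3.0, 15.0)),
        "drinking_days": dict(kind="lognormal", abstainer=(7.0, 6.0, 7.0),
                              relapser=(7.0, 5.0, 7.0), clip=(0.0, 7.0)),
        "daily_alcohol": dict(kind="normal", abstainer=(103.8, 34.9), relapser=(140.0, 74.0)),
        "handedness": dict(kind="lognormal", abstainer=(100.0, 80.0, 100.0),
                           relapser=(100.0, 80.0, 100.0), clip=(-100.0, 100.0)),
        "education": dict(kind="lognormal", abstainer=(12.0, 12.0, 14.3),
                          relapser=(12.0, 12.0, 14.0)),
        "sighd17": dict(kind="lognormal", abstainer=(3.5, 2.0, 6.0), relapser=(6.0, 1.0, 8.0)),
        # the abstainer BDI-II IQR as printed (9.0-9.3) excludes its own median;
        # spread borrowed from the relapser quartile ratio instead
        "bdi_ii": dict(kind="lognormal", abstainer=(11.5, 8.2, 16.1),
                       relapser=(12.0, 7.0, 18.0)),
        "arrs_sv": dict(kind="normal", abstainer=(14.8, 4.5), relapser=(14.9, 4.1)),
        "bis_11": dict(kind="normal", abstainer=(62.0, 9.8), relapser=(63.6, 14.0)),
        "audit": dict(kind="normal", abstainer=(21.3, 7.0), relapser=(23.2, 6.8)),
    }


def _default_risk() -> dict:
    return {
        "lambda": dict(kind="lognormal", abstainer=(0.241, 0.114, 0.525),
                       relapser=(0.530, 0.422, 0.996)),
        "gamma": dict(median=1.0, sigma=0.25),   # configured null: no group difference
        "tau": dict(median=10.0, sigma=0.4),     # nuisance: choice consistency ~80-90%
    }


def _default_region_truth() -> dict:
    """Normal (mean, sd) truths for the processed contrast / VFT integrals.

    Right-frontotemporal go/no-go contrast carries the injected group effect
    (relapsers lower); other regions and all VFT integrals are nulls.  SDs for
    the injected effect derive from the reported IQRs (IQR / 1.349).
    """
    iqr_to_sd = 1.0 / (2 * _Z75)
    return {
        "contrast": {
            "frontopolar": dict(abstainer=(10.0, 70.0), relapser=(10.0, 70.0)),
            "left_frontotemporal": dict(abstainer=(10.0, 70.0), relapser=(10.0, 70.0)),
            "right_frontotemporal": dict(
                abstainer=(30.5, (68.3 - (-35.8)) * iqr_to_sd),
                relapser=(-33.6, (12.7 - (-88.4)) * iqr_to_sd),
            ),
        },
        "vft": {
            region: dict(abstainer=(50.0, 60.0), relapser=(50.0, 60.0))
            for region in ("frontopolar", "left_frontotemporal", "right_frontotemporal")
        },
    }


def _default_behavior() -> dict:
    return {
        "rt_ms": {
            "emotional": dict(abstainer=(724.81, 673.99, 794.98),
                              relapser=(659.81, 621.25, 775.79)),
            "nonemotional": dict(abstainer=(600.29, 555.06, 656.26),
                                 relapser=(528.73, 468.98, 568.33)),
            "control": dict(abstainer=(500.0, 460.0, 545.0), relapser=(500.0, 460.0, 545.0)),
        },
        "rt_trial_sigma": 0.15,
        "false_alarm_prob": dict(abstainer=0.0313, relapser=0.0313),
        "omission_prob": dict(abstainer=0.0625, relapser=0.0313),
        "control_error_prob": 0.02,
        "n_trials_per_run": 32,
        "n_control_runs": 3,
        "vft_words_mean": dict(abstainer=14.5, relapser=14.0),
        "vft_repeat_frac": 0.15,
        "nback": {
            1: dict(p_hit=0.95, p_cr=0.97, rt_ms=(550.0, 0.12), n_trials=24, n_targets=8),
            2: dict(p_hit=0.85, p_cr=0.92, rt_ms=(650.0, 0.12), n_trials=24, n_targets=8),
        },
    }


@dataclass
class CohortConfig:
    n_abstainers: int = 24
    n_relapsers: int = 17
    n_female: dict = field(default_factory=lambda: {"abstainer": 3, "relapser": 3})
    covariates: dict = field(default_factory=_default_covariates)
    risk: dict = field(default_factory=_default_risk)
    region_truth: dict = field(default_factory=_default_region_truth)
    arrs_contrast_rho: dict = field(
        default_factory=lambda: {"abstainer": -0.439, "relapser": -0.067}
    )
    behavior: dict = field(default_factory=_default_behavior)
    fnirs_design: FnirsDesign = field(default_factory=FnirsDesign)
    fnirs_noise: FnirsNoise = field(default_factory=FnirsNoise)
    base_amplitude: tuple[float, float] = (0.8, 0.3)  # neutral-block response amp (mean, sd)
    schedule: decision.ScheduleConfig = field(default_factory=decision.ScheduleConfig)
    lapse_rate: float = 0.02
    no_response_rate: float = 0.01
    # closed-loop mode: relapse assigned by a logistic model on the generated markers
    closed_loop: bool = False
    closed_loop_betas: tuple[float, float, float] = (
        float(logit(17 / 41)), math.log(0.161), math.log(7.037)
    )

    def validate(self) -> None:
        if self.n_abstainers < 2 or self.n_relapsers < 2:
            raise ValueError("group sizes must be >= 2")


def default_config() -> CohortConfig:
    return CohortConfig()


# ---------------------------------------------------------------------------
# covariate and risk-parameter draws
# ---------------------------------------------------------------------------

def _draw_covariate(spec: dict, group: str, n: int, rng: np.random.Generator) -> np.ndarray:
    params = spec[group]
    if spec["kind"] == "normal":
        vals = rng.normal(params[0], params[1], size=n)
    else:
        mu, sigma = lognormal_from_quartiles(*params)
        vals = rng.lognormal(mu, sigma, size=n)
    clip = spec.get("clip")
    if clip is not None:
        vals = np.clip(vals, clip[0], clip[1])
    return vals


def generate_risk_params(
    group: str, config: CohortConfig | None = None, seed: int | np.random.Generator = 0,
    n: int = 1
) -> pd.DataFrame:
    """True (lambda, gamma, tau) draws for ``n`` subjects of one group."""
    config = config or default_config()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_spec = config.risk["lambda"][group]
    mu, sigma = lognormal_from_quartiles(*lam_spec)
    lam = rng.lognormal(mu, sigma, size=n)
    g = config.risk["gamma"]
    gam = rng.lognormal(math.log(g["median"]), g["sigma"], size=n)
    t = config.risk["tau"]
    tau = rng.lognormal(math.log(t["median"]), t["sigma"], size=n)
    return pd.DataFrame({"true_lambda": lam, "true_gamma": gam, "true_tau": tau})


def generate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the participant table and the ground-truth latent table.

    Returns (cohort, truth): ``cohort`` holds group label and observed
    covariates; ``truth`` holds all per-subject latents (risk parameters,
    regional response truths, behavioral response parameters) that the other
    generators consume and that recovery tests compare against.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    n_a, n_r = config.n_abstainers, config.n_relapsers
    n = n_a + n_r

    closed = None
    if config.closed_loop:
        closed = _closed_loop_draw(config, rng, n)
        groups = closed["groups"]
    else:
        groups = np.array(["abstainer"] * n_a + ["relapser"] * n_r)

    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    cohort = pd.DataFrame({"subject_id": subject_ids, "group": groups})
    cohort["relapse"] = (cohort["group"] == "relapser").astype(int)
    truth = pd.DataFrame({"subject_id": subject_ids, "group": groups})

    # sex: exact per-group female counts, scaled if group sizes differ from default
    sex = np.empty(n, dtype=object)
    for grp in ("abstainer", "relapser"):
        idx = np.where(groups == grp)[0]
        n_grp = len(idx)
        ref = {"abstainer": n_a, "relapser": n_r}[grp] if not config.closed_loop else n_grp
        n_f = min(config.n_female[grp] * max(n_grp, 1) // max(ref, 1), n_grp)
        fem = rng.choice(idx, size=n_f, replace=False)
        sex[idx] = "M"
        sex[fem] = "F"
    cohort["sex"] = sex

    # regional truths; ARRS-SV is drawn jointly with the right-FT contrast truth
    rt_spec = config.region_truth["contrast"]["right_frontotemporal"]
    contrast_rft = np.empty(n)
    z_contrast = np.empty(n)
    if closed is not None:
        contrast_rft = closed["contrast"]
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            sub = contrast_rft[idx]
            z_contrast[idx] = (sub - sub.mean()) / max(sub.std(ddof=1), 1e-12)
    else:
        z_contrast = rng.standard_normal(n)
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            m, s = rt_spec[grp]
            contrast_rft[idx] = m + s * z_contrast[idx]
    arrs = np.empty(n)
    arrs_spec = config.covariates["arrs_sv"]
    for grp in ("abstainer", "relapser"):
        idx = groups == grp
        rho = config.arrs_contrast_rho[grp]
        e = rng.standard_normal(idx.sum())
        am, asd = arrs_spec[grp]
        arrs[idx] = am + asd * (rho * z_contrast[idx] + math.sqrt(1 - rho**2) * e)
    truth["true_contrast_right_frontotemporal"] = contrast_rft
    cohort["arrs_sv"] = arrs

    for name, spec in config.covariates.items():
        if name == "arrs_sv":
            continue
        vals = np.empty(n)
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            vals[idx] = _draw_covariate(spec, grp, int(idx.sum()), rng)
        cohort[name] = vals

    for region in ("frontopolar", "left_frontotemporal"):
        spec = config.region_truth["contrast"][region]
        vals = np.empty(n)
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            m, s = spec[grp]
            vals[idx] = rng.normal(m, s, size=int(idx.sum()))
        truth[f"true_contrast_{region}"] = vals
    for region, spec in config.region_truth["vft"].items():
        vals = np.empty(n)
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            m, s = spec[grp]
            vals[idx] = rng.normal(m, s, size=int(idx.sum()))
        truth[f"true_vft_{region}"] = vals

    # risk-preference truths (in closed-loop mode lambda was drawn up front)
    if closed is not None:
        truth["true_lambda"] = closed["lambda"]
        g = config.risk["gamma"]
        truth["true_gamma"] = rng.lognormal(math.log(g["median"]), g["sigma"], size=n)
        t = config.risk["tau"]
        truth["true_tau"] = rng.lognormal(math.log(t["median"]), t["sigma"], size=n)
    else:
        for grp in ("abstainer", "relapser"):
            idx = np.where(groups == grp)[0]
            rp = generate_risk_params(grp, config, rng, n=len(idx))
            for col in rp.columns:
                if col not in truth.columns:
                    truth[col] = np.nan
                truth.loc[idx, col] = rp[col].to_numpy()

    # behavioral truths
    beh = config.behavior
    for block, spec in beh["rt_ms"].items():
        vals = np.empty(n)
        for grp in ("abstainer", "relapser"):
            idx = groups == grp
            mu, sigma = lognormal_from_quartiles(*spec[grp])
            vals[idx] = rng.lognormal(mu, sigma, size=int(idx.sum()))
        truth[f"true_rt_{block}_ms"] = vals
    for name, key in (("true_fa_prob", "false_alarm_prob"), ("true_om_prob", "omission_prob")):
        truth[name] = [beh[key][g] for g in groups]
    truth["true_vft_words"] = [beh["vft_words_mean"][g] for g in groups]
    truth["true_base_amplitude"] = np.maximum(
        rng.normal(*config.base_amplitude, size=n), 0.05
    )
    truth["true_cardiac_freq"] = rng.normal(
        config.fnirs_noise.cardiac_freq_mean, config.fnirs_noise.cardiac_freq_sd, size=n
    )
    return cohort, truth


def _closed_loop_draw(config: CohortConfig, rng: np.random.Generator, n: int) -> dict:
    """Assign relapse from a logistic model on pooled-distribution markers."""
    lam_a = config.risk["lambda"]["abstainer"]
    lam_r = config.risk["lambda"]["relapser"]
    mu = (math.log(lam_a[0]) + math.log(lam_r[0])) / 2
    sig_a = lognormal_from_quartiles(*lam_a)[1]
    sig_r = lognormal_from_quartiles(*lam_r)[1]
    sigma = (sig_a + sig_r) / 2
    lam = rng.lognormal(mu, sigma, size=n)
    spec = config.region_truth["contrast"]["right_frontotemporal"]
    cm = (spec["abstainer"][0] + spec["relapser"][0]) / 2
    cs = (spec["abstainer"][1] + spec["relapser"][1]) / 2
    contrast = rng.normal(cm, cs, size=n)
    z_c = (contrast - contrast.mean()) / contrast.std(ddof=1)
    z_l = (np.log(lam) - np.log(lam).mean()) / np.log(lam).std(ddof=1)
    b0, b_c, b_l = config.closed_loop_betas
    p = expit(b0 + b_c * z_c + b_l * z_l)
    relapse = rng.random(n) < p
    return {
        "groups": np.where(relapse, "relapser", "abstainer"),
        "lambda": lam,
        "contrast": contrast,
    }


# ---------------------------------------------------------------------------
# risk-task choices
# ---------------------------------------------------------------------------

def generate_choices(truth: pd.DataFrame, config: CohortConfig, seed: int = 0) -> pd.DataFrame:
    """Simulate the 120-trial gamble task for every subject; one row per trial."""
    frames = []
    for i, row in enumerate(truth.itertuples(index=False)):
        schedule = decision.build_task_schedule(config.schedule, seed=_sub_seed(seed, i, 0))
        params = decision.RiskPreferenceParams(
            row.true_lambda, row.true_gamma, row.true_tau
        )
        trials = decision.simulate_agent(
            schedule, params, seed=_sub_seed(seed, i, 1),
            lapse_rate=config.lapse_rate, no_response_rate=config.no_response_rate,
        )
        frames.append(decision.trials_to_frame(trials, row.subject_id))
    return pd.concat(frames, ignore_index=True)


def _sub_seed(seed: int, subject_index: int, stream: int) -> int:
    """Deterministic per-subject, per-stream seed below 2**31."""
    return int(
        np.random.SeedSequence([int(seed), subject_index, stream]).generate_state(1)[0]
        % (2**31 - 1)
    )


# ---------------------------------------------------------------------------
# fNIRS recordings
# ---------------------------------------------------------------------------

def _double_gamma_hrf(design: FnirsDesign) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the design rate, peak-normalized."""
    t = np.arange(0, 32.0, design.dt)
    peak = gamma_dist.pdf(t, design.hrf_peak_s)
    under = gamma_dist.pdf(t, design.hrf_undershoot_s)
    h = peak - under / design.hrf_undershoot_ratio
    return h / h.max()


def gonogo_events(design: FnirsDesign) -> list[fnirs.BlockEvent]:
    events = []
    t = design.gonogo_rest_s
    for block in design.gonogo_order:
        events.append(fnirs.BlockEvent(block, t, t + design.gonogo_block_s))
        t += design.gonogo_block_s + design.gonogo_rest_s
    return events


def vft_events(design: FnirsDesign) -> list[fnirs.BlockEvent]:
    on = design.vft_pre_s
    return [fnirs.BlockEvent("vft_production", on, on + design.vft_production_s)]


def _recording_length(design: FnirsDesign, kind: str) -> int:
    if kind == "gonogo":
        dur = (design.gonogo_rest_s + design.gonogo_block_s) * len(design.gonogo_order) \
            + design.gonogo_rest_s
    else:
        dur = design.vft_pre_s + design.vft_production_s + design.vft_post_s
    return int(round(dur / design.dt))


def _block_regressor(design: FnirsDesign, event: fnirs.BlockEvent, n: int) -> np.ndarray:
    box = np.zeros(n)
    i0 = int(round(event.onset_s / design.dt))
    i1 = int(round(event.offset_s / design.dt))
    box[i0:i1] = 1.0
    return np.convolve(box, _double_gamma_hrf(design))[:n] * design.dt


@lru_cache(maxsize=8)
def unit_response_integral(design: FnirsDesign, kind: str = "gonogo") -> float:
    """Processed integral of a unit-amplitude response for one task block.

    Runs the actual processing chain (moving average, two-anchor baseline,
    rectangle integral) on a noise-free recording whose only active block has
    amplitude 1, so generator amplitudes can be set to hit a target contrast
    exactly in the noise-free limit.
    """
    events = gonogo_events(design) if kind == "gonogo" else vft_events(design)
    target = next(e for e in events if e.block_type in ("emotional", "vft_production"))
    n = _recording_length(design, kind)
    series = _block_regressor(design, target, n)
    smooth = fnirs.moving_average(series, window_s=5.0, dt=design.dt)
    duration = n * design.dt
    pre, post = fnirs._baseline_periods(events, target, duration)
    corrected = fnirs.integral_baseline_correct(smooth, pre, post, dt=design.dt)
    return float(fnirs.integral_oxyhb(corrected, (target.onset_s, target.offset_s),
                                      dt=design.dt))


def _pink_noise(rng: np.random.Generator, n: int, sd: float, dt: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    f = np.fft.rfftfreq(n, d=dt)
    spec = rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
    with np.errstate(divide="ignore"):
        spec = spec / np.sqrt(np.where(f > 0, f, np.inf))
    x = np.fft.irfft(spec, n)
    return x * (sd / x.std())


def _motion_spikes(rng: np.random.Generator, n: int, dt: float, rate_per_min: float,
                   amp: float) -> np.ndarray:
    out = np.zeros(n)
    if rate_per_min <= 0 or amp == 0:
        return out
    n_spikes = rng.poisson(rate_per_min * n * dt / 60.0)
    tail = np.exp(-np.arange(0, 2.0, dt) / 0.3)
    for _ in range(n_spikes):
        i = int(rng.integers(n))
        a = amp * (0.5 + rng.exponential(0.5)) * rng.choice([-1.0, 1.0])
        seg = min(len(tail), n - i)
        out[i : i + seg] += a * tail[:seg]
    return out


def generate_fnirs_recording(
    subject: pd.Series,
    design: FnirsDesign | None = None,
    noise: FnirsNoise | None = None,
    seed: int = 0,
    kind: str = "gonogo",
    region_map: dict[str, tuple[int, ...]] | None = None,
) -> fnirs.FnirsRecording:
    """One synthetic recording for one subject (``kind`` = 'gonogo' or 'vft').

    ``subject`` is a row of the truth table.  Per-region block amplitudes are
    back-computed from the subject's target contrast / VFT integral via the
    unit-response integral of the processing chain, so the pipeline recovers
    the configured truth exactly when noise amplitudes are zero.
    """
    design = design or FnirsDesign()
    noise = noise or FnirsNoise()
    region_map = region_map or fnirs.DEFAULT_REGION_MAP
    rng = np.random.default_rng(seed)
    events = gonogo_events(design) if kind == "gonogo" else vft_events(design)
    n = _recording_length(design, kind)
    i_unit = unit_response_integral(design, kind)

    a0 = float(subject["true_base_amplitude"])
    amps: dict[str, dict[str, float]] = {}
    for region in region_map:
        if kind == "gonogo":
            c = float(subject[f"true_contrast_{region}"])
            amps[region] = {
                "control": 0.5 * a0,
                "nonemotional": a0,
                "emotional": a0 + c / i_unit,
            }
        else:
            v = float(subject[f"true_vft_{region}"])
            amps[region] = {"vft_production": v / i_unit}

    regressors = {id(e): _block_regressor(design, e, n) for e in events}
    region_signal = {}
    for region in region_map:
        sig = np.zeros(n)
        for e in events:
            sig += amps[region].get(e.block_type, 0.0) * regressors[id(e)]
        region_signal[region] = sig

    channel_ids = tuple(sorted(ch for chans in region_map.values() for ch in chans))
    ch_region = {ch: r for r, chans in region_map.items() for ch in chans}
    t = np.arange(n) * design.dt
    rows = []
    for ch in channel_ids:
        gain = 1.0 + noise.channel_gain_sd * rng.standard_normal()
        x = gain * region_signal[ch_region[ch]]
        x = x + _pink_noise(rng, n, noise.pink_sd, design.dt)
        if noise.white_sd > 0:
            x = x + rng.normal(0, noise.white_sd, n)
        if noise.cardiac_amp > 0:
            x = x + noise.cardiac_amp * np.sin(
                2 * np.pi * float(subject["true_cardiac_freq"]) * t
                + rng.uniform(0, 2 * np.pi)
            )
        x = x + _motion_spikes(rng, n, design.dt, noise.spike_rate_per_min, noise.spike_amp)
        rows.append(x)
    return fnirs.FnirsRecording(
        subject_id=str(subject["subject_id"]),
        channel_ids=channel_ids,
        oxy_hb=np.vstack(rows),
        events=events,
        sampling_interval=design.dt,
    )


# ---------------------------------------------------------------------------
# behavioral logs
# ---------------------------------------------------------------------------

def generate_behavior_logs(
    subject: pd.Series, config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Go/no-go, n-back, and VFT logs for one subject (rows of the truth table)."""
    config = config or default_config()
    beh = config.behavior
    rng = np.random.default_rng(seed)
    sid = str(subject["subject_id"])
    n_per_run = beh["n_trials_per_run"]
    n_go = n_per_run // 2

    gonogo_rows = []
    runs = [("emotional", 0), ("nonemotional", 0)] + [
        ("control", r) for r in range(beh["n_control_runs"])
    ]
    for block, run in runs:
        if block == "control":
            p_om = p_fa = beh["control_error_prob"]
        else:
            p_fa = float(subject["true_fa_prob"])
            p_om = float(subject["true_om_prob"])
        rt_med = float(subject[f"true_rt_{block}_ms"])
        types = np.array(["go"] * n_go + ["nogo"] * (n_per_run - n_go))
        rng.shuffle(types)
        for k, tt in enumerate(types):
            responded = rng.random() >= p_om if tt == "go" else rng.random() < p_fa
            rt = float(rng.lognormal(math.log(rt_med), beh["rt_trial_sigma"])) \
                if responded else np.nan
            gonogo_rows.append(dict(subject_id=sid, task="gonogo", block=block, run=run,
                                    trial_index=k, trial_type=tt, stimulus=f"{block}_{tt}",
                                    responded=responded, rt_ms=rt))
    gonogo = pd.DataFrame(gonogo_rows)

    nback_rows = []
    for load, spec in beh["nback"].items():
        targets = np.zeros(spec["n_trials"], dtype=bool)
        targets[rng.choice(spec["n_trials"], size=spec["n_targets"], replace=False)] = True
        for k, is_t in enumerate(targets):
            responded = rng.random() < (spec["p_hit"] if is_t else 1 - spec["p_cr"])
            rt = float(rng.lognormal(math.log(spec["rt_ms"][0]), spec["rt_ms"][1])) \
                if responded else np.nan
            nback_rows.append(dict(subject_id=sid, task="nback", load=load, trial_index=k,
                                   is_target=bool(is_t), responded=bool(responded), rt_ms=rt))
    nback = pd.DataFrame(nback_rows)

    n_valid = int(rng.poisson(float(subject["true_vft_words"])))
    vft_rows = []
    word_idx = 0
    for k in range(n_valid):
        vft_rows.append(dict(subject_id=sid, task="vft", block=int(rng.integers(3)),
                             word_key=f"{sid}_w{word_idx:03d}"))
        word_idx += 1
    n_repeats = rng.binomial(max(n_valid, 1), beh["vft_repeat_frac"])
    for _ in range(n_repeats):
        if n_valid == 0:
            break
        dup = int(rng.integers(n_valid))
        vft_rows.append(dict(subject_id=sid, task="vft", block=int(rng.integers(3)),
                             word_key=f"{sid}_w{dup:03d}"))
    vft = pd.DataFrame(vft_rows, columns=["subject_id", "task", "block", "word_key"])
    return gonogo, nback, vft


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cohort: pd.DataFrame
    truth: pd.DataFrame
    choices: pd.DataFrame
    gonogo: pd.DataFrame
    nback: pd.DataFrame
    vft: pd.DataFrame
    recordings: dict[str, dict[str, fnirs.FnirsRecording]]
    seed: int


def generate_dataset(
    config: CohortConfig | None = None, seed: int = 0, with_fnirs: bool = True
) -> SyntheticDataset:
    """Generate the complete synthetic study: cohort, truths, and all raw streams."""
    config = config or default_config()
    cohort, truth = generate_cohort(config, seed)
    choices = generate_choices(truth, config, seed)
    gonogo_frames, nback_frames, vft_frames = [], [], []
    recordings: dict[str, dict[str, fnirs.FnirsRecording]] = {}
    for i, (_, subject) in enumerate(truth.iterrows()):
        g, nb, vf = generate_behavior_logs(subject, config, seed=_sub_seed(seed, i, 2))
        gonogo_frames.append(g)
        nback_frames.append(nb)
        vft_frames.append(vf)
        if with_fnirs:
            recordings[str(subject["subject_id"])] = {
                "gonogo": generate_fnirs_recording(
                    subject, config.fnirs_design, config.fnirs_noise,
                    seed=_sub_seed(seed, i, 3), kind="gonogo",
                ),
                "vft": generate_fnirs_recording(
                    subject, config.fnirs_design, config.fnirs_noise,
                    seed=_sub_seed(seed, i, 4), kind="vft",
                ),
            }
    return SyntheticDataset(
        cohort=cohort,
        truth=truth,
        choices=choices,
        gonogo=pd.concat(gonogo_frames, ignore_index=True),
        nback=pd.concat(nback_frames, ignore_index=True),
        vft=pd.concat(vft_frames, ignore_index=True),
        recordings=recordings,
        seed=seed,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset as CSVs plus per-recording CSV + JSON sidecars and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.cohort.to_csv(outdir / "cohort.csv", index=False)
    ds.truth.to_csv(outdir / "truth.csv", index=False)
    ds.choices.to_csv(outdir / "choices.csv", index=False)
    ds.gonogo.to_csv(outdir / "gonogo.csv", index=False)
    ds.nback.to_csv(outdir / "nback.csv", index=False)
    ds.vft.to_csv(outdir / "vft.csv", index=False)
    fdir = outdir / "fnirs"
    fdir.mkdir(exist_ok=True)
    for sid, recs in ds.recordings.items():
        for kind, rec in recs.items():
            df, sidecar = fnirs.recording_to_frame(rec)
            df.to_csv(fdir / f"{sid}_{kind}.csv", index=False)
            (fdir / f"{sid}_{kind}.json").write_text(json.dumps(sidecar))
    manifest = {"seed": ds.seed, "n_subjects": len(ds.cohort)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
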