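"""Block-design oxy-Hb processing in "integral mode".

Multichannel oxy-Hb series (0.1 s sampling, channels 22..52 over the frontal
and temporal cortex) are smoothed with a 5 s centered moving average,
artifact channels are rejected by deterministic criteria (rhythmic band power,
amplitude spikes, flatline), and each task block is baseline-corrected by
subtracting the line through two anchors: the mean of the last 10 s of the
pre-task period and the mean of the last 10 s of the post-task period, each
anchored at the center of its averaging window.  Activation per block is the
integral (rectangle rule) of the corrected series over the block; channel
integrals are averaged within three regions (frontopolar, left and right
frontotemporal) and the emotional-minus-neutral contrast is formed per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "DEFAULT_REGION_MAP",
    "BlockEvent",
    "FnirsRecording",
    "RegionActivation",
    "ArtifactCriteria",
    "moving_average",
    "reject_artifact_channels",
    "integral_baseline_correct",
    "integral_oxyhb",
    "region_integral",
    "emotion_contrast",
    "process_recording",
    "dominant_cardiac_frequency",
    "recording_to_frame",
    "frame_to_recording",
]

#: channel -> region assignment for the 31 frontotemporal channels (22..52)
DEFAULT_REGION_MAP: dict[str, tuple[int, ...]] = {
    "frontopolar": (25, 26, 27, 28, 36, 37, 38, 46, 47, 48, 49),
    "left_frontotemporal": (29, 30, 31, 39, 40, 41, 42, 50, 51, 52),
    "right_frontotemporal": (22, 23, 24, 32, 33, 34, 35, 43, 44, 45),
}

TASK_BLOCK_TYPES = ("emotional", "nonemotional", "control", "vft_production")


@dataclass(frozen=True)
class BlockEvent:
    block_type: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")


@dataclass
class FnirsRecording:
    """Channels x time oxy-Hb series with block events at fixed 0.1 s sampling."""

    subject_id: str
    channel_ids: tuple[int, ...]
    oxy_hb: np.ndarray  # shape (n_channels, n_samples)
    events: list[BlockEvent]
    sampling_interval: float = 0.1

    def __post_init__(self) -> None:
        self.oxy_hb = np.asarray(self.oxy_hb, dtype=float)
        if self.oxy_hb.ndim != 2 or self.oxy_hb.shape[0] != len(self.channel_ids):
            raise ValueError("oxy_hb must be (n_channels, n_samples)")

    @property
    def duration_s(self) -> float:
        return self.oxy_hb.shape[1] * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.oxy_hb.shape[1]) * self.sampling_interval


@dataclass
class RegionActivation:
    subject_id: str
    region: str
    condition: str
    integral_oxyhb: float | None
    n_channels_used: int
    contrast_emotional_minus_neutral: float | None = None


@dataclass(frozen=True)
class ArtifactCriteria:
    """Deterministic channel-rejection thresholds.

    ``rhythmic_band`` covers motion/cardiac-range oscillations; a channel whose
    band-power fraction there exceeds ``rhythmic_power_max`` is rejected.
    Spikes are samples beyond ``spike_z`` robust (MAD) z-units; channels with
    more than ``spike_fraction_max`` such samples are rejected.  Channels with
    standard deviation below ``flatline_sd`` carry no signal.
    """

    rhythmic_band: tuple[float, float] = (0.6, 2.5)
    rhythmic_power_max: float = 0.5
    spike_z: float = 6.0
    spike_fraction_max: float = 0.01
    flatline_sd: float = 1e-10


# ---------------------------------------------------------------------------
# filtering and baseline
# ---------------------------------------------------------------------------

def moving_average(series: np.ndarray, window_s: float = 5.0, dt: float = 0.1) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Window length is rounded to an odd number of samples (5 s at 0.1 s
    sampling -> 51 samples), so constant and, away from the edges, affine
    signals pass through unchanged.  Accepts 1-D (time,) or 2-D
    (channels, time) input.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    if window_s < dt:
        raise ValueError("window must be at least one sampling interval")
    n = int(round(window_s / dt))
    if n % 2 == 0:
        n += 1
    half = n // 2

    def _ma1d(x: np.ndarray) -> np.ndarray:
        csum = np.concatenate(([0.0], np.cumsum(x)))
        idx = np.arange(len(x))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, len(x) - 1)
        return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)

    if series.ndim == 1:
        return _ma1d(series)
    return np.vstack([_ma1d(row) for row in series])


def integral_baseline_correct(
    series: np.ndarray,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    dt: float = 0.1,
    anchor_s: float = 10.0,
    task_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Subtract the line joining the pre- and post-task baseline anchors.

    Each anchor is the mean of the last ``anchor_s`` seconds of its window,
    placed at the center of that averaging span.  Applying the correction a
    second time is a no-op (both anchor means become 0).
    """
    series = np.asarray(series, dtype=float)
    for name, (a, b) in (("pre", pre_window), ("post", post_window)):
        if b - a < anchor_s - 1e-9:
            raise ValueError(f"{name}_window shorter than the {anchor_s} s anchor span")
    if task_window is not None:
        t0, t1 = task_window
        if pre_window[1] > t0 + 1e-9 or post_window[0] < t1 - 1e-9:
            raise ValueError("baseline windows overlap the task period")

    t = np.arange(series.shape[-1]) * dt

    def anchor(win):
        a = win[1] - anchor_s
        mask = (t >= a - 1e-9) & (t < win[1] - 1e-9)
        if not mask.any():
            raise ValueError("baseline anchor window outside the series")
        # exact sample-time centroid keeps affine signals exactly annihilated
        return float(t[mask].mean()), series[..., mask].mean(axis=-1)

    t1c, m1 = anchor(pre_window)
    t2c, m2 = anchor(post_window)
    slope = (m2 - m1) / (t2c - t1c)
    line = np.expand_dims(m1, -1) + np.expand_dims(slope, -1) * (t - t1c) if series.ndim > 1 \
        else m1 + slope * (t - t1c)
    return series - line


def integral_oxyhb(series: np.ndarray, task_window: tuple[float, float], dt: float = 0.1) -> float:
    """Rectangle-rule integral of the corrected series over the task window (conc * s)."""
    series = np.asarray(series, dtype=float)
    t = np.arange(series.shape[-1]) * dt
    mask = (t >= task_window[0] - 1e-9) & (t < task_window[1] - 1e-9)
    if not mask.any():
        raise ValueError("empty task window")
    return float(np.sum(series[..., mask], axis=-1).item() * dt) if series.ndim == 1 else \
        np.sum(series[..., mask], axis=-1) * dt


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------

def reject_artifact_channels(
    recording: FnirsRecording, criteria: ArtifactCriteria | None = None
) -> tuple[np.ndarray, dict[int, str]]:
    """Per-channel keep mask plus rejection reasons.

    Reasons: ``flatline`` (no variance), ``rhythmic_power`` (band-power
    fraction in the rhythmic band above threshold), ``amplitude_spike``
    (too many extreme robust-z samples).
    """
    criteria = criteria or ArtifactCriteria()
    if recording.duration_s < 10.0:
        raise ValueError("need at least 10 s of data for artifact screening")
    fs = 1.0 / recording.sampling_interval
    keep = np.ones(len(recording.channel_ids), dtype=bool)
    reasons: dict[int, str] = {}
    for i, ch in enumerate(recording.channel_ids):
        x = recording.oxy_hb[i]
        if np.std(x) < criteria.flatline_sd:
            keep[i] = False
            reasons[ch] = "flatline"
            continue
        f, pxx = sps.welch(x - x.mean(), fs=fs, nperseg=min(1024, len(x)))
        total = np.trapezoid(pxx[1:], f[1:])
        band = (f >= criteria.rhythmic_band[0]) & (f <= criteria.rhythmic_band[1])
        band_frac = np.trapezoid(pxx[band], f[band]) / total if total > 0 else 0.0
        if band_frac > criteria.rhythmic_power_max:
            keep[i] = False
            reasons[ch] = "rhythmic_power"
            continue
        # spikes are fast transients: screen the residual after 5 s smoothing
        resid = x - moving_average(x, window_s=5.0, dt=recording.sampling_interval)
        med = np.median(resid)
        mad = np.median(np.abs(resid - med)) * 1.4826
        # floor the scale at a fraction of the overall channel amplitude so a
        # noise-free smooth signal (near-zero residual MAD) is never flagged
        mad = max(mad, 0.05 * float(np.std(x)))
        if mad > 0:
            z = np.abs(resid - med) / mad
            if np.mean(z > criteria.spike_z) > criteria.spike_fraction_max:
                keep[i] = False
                reasons[ch] = "amplitude_spike"
    return keep, reasons


def dominant_cardiac_frequency(
    recording: FnirsRecording, band: tuple[float, float] = (0.6, 2.5)
) -> float:
    """QC output: frequency of the spectral peak in the cardiac band, averaged over channels."""
    fs = 1.0 / recording.sampling_interval
    x = recording.oxy_hb - recording.oxy_hb.mean(axis=1, keepdims=True)
    f, pxx = sps.welch(x, fs=fs, nperseg=min(2048, x.shape[1]))
    mask = (f >= band[0]) & (f <= band[1])
    return float(f[mask][np.argmax(pxx[:, mask].mean(axis=0))])


# ---------------------------------------------------------------------------
# regional aggregation
# ---------------------------------------------------------------------------

def region_integral(
    channel_integrals: dict[int, float],
    region_map: dict[str, tuple[int, ...]] | None = None,
    keep_mask: dict[int, bool] | None = None,
) -> dict[str, tuple[float | None, int]]:
    """Mean channel integral per region over kept channels; (None, 0) if none survive."""
    region_map = region_map or DEFAULT_REGION_MAP
    mapped = {ch for chans in region_map.values() for ch in chans}
    unknown = set(channel_integrals) - mapped
    if unknown:
        raise ValueError(f"channels not in region map: {sorted(unknown)}")
    out: dict[str, tuple[float | None, int]] = {}
    for region, chans in region_map.items():
        vals = [
            channel_integrals[ch]
            for ch in chans
            if ch in channel_integrals and (keep_mask is None or keep_mask.get(ch, True))
        ]
        out[region] = (float(np.mean(vals)), len(vals)) if vals else (None, 0)
    return out


def emotion_contrast(emotional: RegionActivation, neutral: RegionActivation) -> float:
    """Emotional-minus-neutral integral for one subject and region."""
    if emotional.region != neutral.region or emotional.subject_id != neutral.subject_id:
        raise ValueError("contrast requires matching subject and region")
    if emotional.integral_oxyhb is None or neutral.integral_oxyhb is None:
        raise ValueError("missing region value")
    return emotional.integral_oxyhb - neutral.integral_oxyhb


# ---------------------------------------------------------------------------
# end-to-end per-recording processing
# ---------------------------------------------------------------------------

def _baseline_periods(events: list[BlockEvent], block: BlockEvent, duration: float):
    """Pre/post baseline periods = gaps between this block and its neighbours."""
    onsets = sorted(events, key=lambda e: e.onset_s)
    prev_off = 0.0
    next_on = duration
    for e in onsets:
        if e is block:
            continue
        if e.offset_s <= block.onset_s + 1e-9:
            prev_off = max(prev_off, e.offset_s)
        if e.onset_s >= block.offset_s - 1e-9:
            next_on = min(next_on, e.onset_s)
    return (prev_off, block.onset_s), (block.offset_s, next_on)


def process_recording(
    recording: FnirsRecording,
    region_map: dict[str, tuple[int, ...]] | None = None,
    criteria: ArtifactCriteria | None = None,
    window_s: float = 5.0,
    conditions: tuple[str, ...] = ("emotional", "nonemotional", "vft_production"),
) -> list[RegionActivation]:
    """Full integral-mode pipeline for one recording.

    Rejects artifact channels, smooths, and for each task block of the
    requested conditions computes per-channel baseline-corrected integrals,
    averages them within regions, and (when both emotional and nonemotional
    blocks are present) appends the emotional-minus-neutral contrast.
    """
    region_map = region_map or DEFAULT_REGION_MAP
    dt = recording.sampling_interval
    keep_arr, _reasons = reject_artifact_channels(recording, criteria)
    keep = {ch: bool(k) for ch, k in zip(recording.channel_ids, keep_arr)}
    smooth = moving_average(recording.oxy_hb, window_s=window_s, dt=dt)

    per_condition: dict[str, dict[str, tuple[float | None, int]]] = {}
    for cond in conditions:
        blocks = [e for e in recording.events if e.block_type == cond]
        if not blocks:
            continue
        # average integrals over repeated blocks of the same condition
        sums: dict[int, list[float]] = {ch: [] for ch in recording.channel_ids}
        for block in blocks:
            pre, post = _baseline_periods(recording.events, block, recording.duration_s)
            corrected = integral_baseline_correct(
                smooth, pre, post, dt=dt, task_window=(block.onset_s, block.offset_s)
            )
            integ = integral_oxyhb(corrected, (block.onset_s, block.offset_s), dt=dt)
            for ch, v in zip(recording.channel_ids, np.atleast_1d(integ)):
                sums[ch].append(float(v))
        chan_int = {ch: float(np.mean(v)) for ch, v in sums.items() if v}
        per_condition[cond] = region_integral(chan_int, region_map, keep)
        if all(not keep[ch] for ch in recording.channel_ids):
            warnings.warn("all channels rejected; region values missing", stacklevel=2)

    activations: list[RegionActivation] = []
    for cond, regions in per_condition.items():
        for region, (val, n_used) in regions.items():
            act = RegionActivation(recording.subject_id, region, cond, val, n_used)
            if cond == "emotional" and "nonemotional" in per_condition:
                neu, _ = per_condition["nonemotional"][region]
                if val is not None and neu is not None:
                    act.contrast_emotional_minus_neutral = val - neu
            activations.append(act)
    return activations


# ---------------------------------------------------------------------------
# tabular I/O (time-series CSV + JSON sidecar)
# ---------------------------------------------------------------------------

def recording_to_frame(recording: FnirsRecording) -> tuple[pd.DataFrame, dict]:
    df = pd.DataFrame({"time_s": recording.times})
    for i, ch in enumerate(recording.channel_ids):
        df[f"ch{ch}"] = recording.oxy_hb[i]
    sidecar = {
        "subject_id": recording.subject_id,
        "sampling_interval_s": recording.sampling_interval,
        "events": [
            {"type": e.block_type, "onset_s": e.onset_s, "offset_s": e.offset_s}
            for e in recording.events
        ],
    }
    return df, sidecar


def frame_to_recording(df: pd.DataFrame, sidecar: dict) -> FnirsRecording:
    chan_cols = [c for c in df.columns if c.startswith("ch")]
    channel_ids = tuple(int(c[2:]) for c in chan_cols)
    events = [
        BlockEvent(e["type"], float(e["onset_s"]), float(e["offset_s"]))
        for e in sidecar["events"]
    ]
    return FnirsRecording(
        subject_id=str(sidecar["subject_id"]),
        channel_ids=channel_ids,
        oxy_hb=df[chan_cols].to_numpy().T,
        events=events,
        sampling_interval=float(sidecar.get("sampling_interval_s", 0.1)),
    )
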