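"""Scoring of the emotional go/no-go, n-back, and verbal fluency (VFT) logs.

Go/no-go blocks (32 trials, 50% go) yield a false-alarm rate (responses on
no-go trials / all no-go trials), an omission rate (non-responses on go
trials / all go trials), and the mean reaction time over correct hits.
N-back performance is percent correct (hits on targets plus correct rejections
on non-targets) and mean RT over correct hits, per memory load.  VFT output is
the number of distinct words across the three 20 s production blocks, where
repeats and inflected variants of an earlier word share one inflection-group
key and count once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GoNogoTrial",
    "GoNogoBlockScore",
    "NbackScore",
    "score_gonogo",
    "score_nback",
    "score_vft",
    "gonogo_frame_to_trials",
]

GONOGO_BLOCKS = ("emotional", "nonemotional", "control")


@dataclass
class GoNogoTrial:
    block: str
    trial_type: str  # "go" | "nogo"
    stimulus: str
    responded: bool
    rt_ms: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in ("go", "nogo"):
            raise ValueError(f"trial_type must be 'go' or 'nogo', got {self.trial_type!r}")
        if self.responded and (self.rt_ms is None or not self.rt_ms > 0):
            raise ValueError("responded trials need a positive rt_ms")
        if not self.responded and self.rt_ms is not None:
            raise ValueError("rt_ms present without a response")


@dataclass
class GoNogoBlockScore:
    block: str
    false_alarm_rate: float | None
    omission_error_rate: float | None
    mean_rt_correct_hits_ms: float | None
    n_go: int
    n_nogo: int


@dataclass
class NbackScore:
    load: int
    percent_correct: float
    mean_rt_ms: float | None
    n_trials: int


def score_gonogo(trials: list[GoNogoTrial]) -> dict[str, GoNogoBlockScore]:
    """Per-block error rates and hit RT.

    A block missing either go or no-go trials gets missing (None) rates rather
    than an error: partial logs still score what they can.
    """
    scores: dict[str, GoNogoBlockScore] = {}
    blocks = sorted({t.block for t in trials})
    for block in blocks:
        bt = [t for t in trials if t.block == block]
        go = [t for t in bt if t.trial_type == "go"]
        nogo = [t for t in bt if t.trial_type == "nogo"]
        fa = sum(t.responded for t in nogo) / len(nogo) if nogo else None
        om = sum(not t.responded for t in go) / len(go) if go else None
        hit_rts = [t.rt_ms for t in go if t.responded]
        rt = float(np.mean(hit_rts)) if hit_rts else None
        scores[block] = GoNogoBlockScore(block, fa, om, rt, len(go), len(nogo))
    return scores


def score_nback(trials: pd.DataFrame) -> dict[int, NbackScore]:
    """Percent correct and hit RT per load from a trial log.

    Expects columns: load, is_target (bool), responded (bool), rt_ms.
    Correct = response on a target or withheld response on a non-target.
    """
    if len(trials) == 0:
        raise ValueError("empty n-back log")
    out: dict[int, NbackScore] = {}
    for load, grp in trials.groupby("load"):
        correct = np.where(grp["is_target"], grp["responded"], ~grp["responded"].astype(bool))
        hits = grp[grp["is_target"] & grp["responded"]]
        rt = float(hits["rt_ms"].mean()) if len(hits) else None
        out[int(load)] = NbackScore(
            load=int(load),
            percent_correct=float(100.0 * np.mean(correct)),
            mean_rt_ms=rt,
            n_trials=len(grp),
        )
    return out


def score_vft(word_events: list[tuple[str, int]] | pd.DataFrame) -> int:
    """Count distinct inflection-group keys across the production blocks.

    ``word_events`` is a list of (inflection_group_key, block_index) pairs or
    a DataFrame with columns ``word_key`` and ``block``.  Repeats and
    inflected variants share a key and count once; no linguistic processing
    happens here — keys are taken as given.
    """
    if isinstance(word_events, pd.DataFrame):
        keys = word_events["word_key"].tolist()
    else:
        keys = [k for k, _ in word_events]
    return len(set(keys))


def gonogo_frame_to_trials(df: pd.DataFrame) -> list[GoNogoTrial]:
    """Build trials from a log with columns block, trial_type, stimulus, responded, rt_ms."""
    trials = []
    for row in df.itertuples(index=False):
        responded = bool(row.responded)
        rt = float(row.rt_ms) if responded and not pd.isna(row.rt_ms) else None
        trials.append(GoNogoTrial(str(row.block), str(row.trial_type), str(row.stimulus),
                                  responded, rt))
    return trials
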