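#!/usr/bin/env python
"""Score the go/no-go, n-back, and VFT logs into per-subject summary measures."""

import argparse
from pathlib import Path

import pandas as pd

from relapsekit import behavior as bh


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/behavior_summary.csv")
    args = ap.parse_args()

    data = Path(args.data)
    gonogo = pd.read_csv(data / "gonogo.csv")
    nback = pd.read_csv(data / "nback.csv")
    vft = pd.read_csv(data / "vft.csv")

    rows = []
    for sid, grp in gonogo.groupby("subject_id"):
        scores = bh.score_gonogo(bh.gonogo_frame_to_trials(grp))
        row = {"subject_id": sid}
        if "emotional" in scores:
            row["fa_rate_emotional"] = scores["emotional"].false_alarm_rate
            row["omission_rate_emotional"] = scores["emotional"].omission_error_rate
            row["rt_emotional_ms"] = scores["emotional"].mean_rt_correct_hits_ms
        if "nonemotional" in scores:
            row["rt_nonemotional_ms"] = scores["nonemotional"].mean_rt_correct_hits_ms
        for load, sc in bh.score_nback(nback[nback.subject_id == sid]).items():
            row[f"nback{load}_pct"] = sc.percent_correct
            row[f"nback{load}_rt_ms"] = sc.mean_rt_ms
        row["vft_words"] = bh.score_vft(vft[vft.subject_id == sid])
        rows.append(row)
    out = pd.DataFrame(rows)
    out.to_csv(args.out, index=False)
    print(f"scored {len(out)} subjects -> {args.out}")
    print(f"non-emotional RT median: {out.rt_nonemotional_ms.median():.1f} ms; "
          f"VFT words median: {out.vft_words.median():.1f}")


if __name__ == "__main__":
    main()
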