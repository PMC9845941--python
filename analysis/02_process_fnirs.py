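#!/usr/bin/env python
"""Integral-mode fNIRS processing for every recording in the generated dataset.

Reads the CSV + JSON recordings written by 01_generate_cohort.py, rejects
artifact channels, computes per-region integral oxy-Hb per condition and the
emotional-minus-neutral contrast, and writes results/activations.csv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from relapsekit import fnirs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/activations.csv")
    args = ap.parse_args()

    rows = []
    rejected = 0
    for rec_csv in sorted(Path(args.data, "fnirs").glob("*.csv")):
        sidecar = json.loads(rec_csv.with_suffix(".json").read_text())
        rec = fnirs.frame_to_recording(pd.read_csv(rec_csv), sidecar)
        _, reasons = fnirs.reject_artifact_channels(rec)
        rejected += len(reasons)
        conds = ("vft_production",) if "vft" in rec_csv.stem else ("emotional",
                                                                   "nonemotional")
        for a in fnirs.process_recording(rec, conditions=conds):
            rows.append(dict(subject_id=a.subject_id, region=a.region,
                             condition=a.condition, integral_oxyhb=a.integral_oxyhb,
                             contrast=a.contrast_emotional_minus_neutral,
                             n_channels_used=a.n_channels_used))
    out = pd.DataFrame(rows)
    out.to_csv(args.out, index=False)
    emo = out[(out.condition == "emotional") & (out.region == "right_frontotemporal")]
    print(f"{len(out)} region/condition rows from {out.subject_id.nunique()} subjects "
          f"({rejected} channels rejected) -> {args.out}")
    print(f"right-FT contrast: median {emo.contrast.median():.1f}")


if __name__ == "__main__":
    main()
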