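#!/usr/bin/env python
"""Generate the synthetic study cohort and write all raw data streams.

Produces a 24-abstainer / 17-relapser cohort with calibrated covariates,
ground-truth risk parameters, gamble-choice logs, go/no-go / n-back / VFT
logs, and multichannel fNIRS recordings under results/data/.
"""

import argparse

from relapsekit import synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    ds = synth.generate_dataset(seed=args.seed)
    synth.write_dataset(ds, args.out)
    counts = ds.cohort.group.value_counts()
    print(f"wrote {len(ds.cohort)} subjects ({counts.get('abstainer', 0)} abstainers, "
          f"{counts.get('relapser', 0)} relapsers) to {args.out}")
    print(f"choice rows: {len(ds.choices)}; go/no-go rows: {len(ds.gonogo)}; "
          f"recordings: {2 * len(ds.recordings)}")


if __name__ == "__main__":
    main()
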