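#!/usr/bin/env python
"""Group comparisons, craving correlation, and the logistic prognosis model.

Joins the outputs of steps 01-04 into the one-row-per-subject analysis table,
then writes the comparison tables, the logistic model, and the report figures.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from relapsekit import pipeline, plots, stats, synth


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/report")
    args = ap.parse_args()

    data = Path(args.data)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cohort = pd.read_csv(data / "cohort.csv")
    activations = pd.read_csv(data.parent / "activations.csv")
    behavior = pd.read_csv(data.parent / "behavior_summary.csv")
    fits = pd.read_csv(data.parent / "fits.csv")

    emo = activations[activations.condition == "emotional"]
    contrasts = emo.pivot(index="subject_id", columns="region", values="contrast")
    contrasts.columns = [f"contrast_{c}" for c in contrasts.columns]
    vft = activations[activations.condition == "vft_production"]
    vft_t = vft.pivot(index="subject_id", columns="region", values="integral_oxyhb")
    vft_t.columns = [f"vft_{c}" for c in vft_t.columns]

    table = (cohort
             .merge(contrasts.reset_index(), on="subject_id", how="left")
             .merge(vft_t.reset_index(), on="subject_id", how="left")
             .merge(behavior, on="subject_id", how="left")
             .merge(fits[["subject_id", "lambda", "gamma", "tau"]], on="subject_id",
                    how="left"))
    table.to_csv(out / "analysis_table.csv", index=False)

    report = stats.run_group_analysis(table)
    for name, obj in report.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(pipeline._jsonable(report["summary"]), indent=2, sort_keys=True)
    )
    plots.write_report_figures(table, out)

    s = report["summary"]
    print(f"lambda: medians {s.get('abstainer_lambda_median', float('nan')):.3f} vs "
          f"{s.get('relapser_lambda_median', float('nan')):.3f}, "
          f"p = {s.get('lambda_p', float('nan')):.4f}")
    print(f"right-FT contrast: medians "
          f"{s.get('abstainer_rft_contrast_median', float('nan')):.1f} vs "
          f"{s.get('relapser_rft_contrast_median', float('nan')):.1f}, "
          f"p = {s.get('rft_contrast_p', float('nan')):.4f}")
    print(f"logistic ORs: contrast {s.get('or_contrast_right_frontotemporal', float('nan')):.3f}, "
          f"lambda {s.get('or_lambda', float('nan')):.3f}; "
          f"sens/spec {s.get('sensitivity_pct', float('nan')):.1f}/"
          f"{s.get('specificity_pct', float('nan')):.1f}%")
    print(f"report -> {out}")


if __name__ == "__main__":
    main()
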