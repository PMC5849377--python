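"""Validate the model on the synthetic series: lagged Pearson and ROC/AUC.

Reads results/synthetic_series.csv, writes results/validation.json plus a
tidy results/roc_table.csv (AUC and 95% CI per predictor and lag), and
prints the per-lag correlation between model predictions and counts.
"""

from pathlib import Path

from fuzzyair.io import read_series_csv
from fuzzyair.model import build_hospitalization_fis
from fuzzyair.validation import validate

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = read_series_csv(RESULTS / "synthetic_series.csv", require_counts=True)
    fis = build_hospitalization_fis()
    report = validate(series, fis)

    (RESULTS / "validation.json").write_text(report.to_json() + "\n")
    report.to_frame().to_csv(RESULTS / "roc_table.csv", index=False,
                             float_format="%.3f")

    print("Pearson correlation, model prediction (day t) vs observed counts (day t+lag):")
    for c in report.correlations:
        print(f"  lag {c.lag}: r = {c.pearson_r:.3f} (p = {c.p_value:.3g}, n = {c.n_pairs})")
    print(f"\nROC AUC at cutoff > {report.cutoff} hospitalizations "
          f"({report.ci_method} 95% CI):")
    for r in report.roc:
        print(f"  {r.predictor:<17} lag {r.lag}: "
              f"{r.auc:.3f} ({r.ci_low:.3f} - {r.ci_high:.3f})")


if __name__ == "__main__":
    main()
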