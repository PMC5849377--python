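"""Run the 16-rule fuzzy model over the synthetic series day by day.

Reads results/synthetic_series.csv, writes results/predictions.csv, and
prints the predicted-count descriptives alongside the observed counts.
"""

from pathlib import Path

from fuzzyair.io import read_series_csv, write_predictions_csv
from fuzzyair.model import build_hospitalization_fis, predict_series

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series = read_series_csv(RESULTS / "synthetic_series.csv", require_counts=True)
    fis = build_hospitalization_fis()
    preds = predict_series(fis, series)
    out = RESULTS / "predictions.csv"
    write_predictions_csv(series["date"], preds.to_numpy(), out)

    print(f"wrote {preds.notna().sum()} daily predictions to {out}")
    print(f"predicted: mean {preds.mean():.2f}, sd {preds.std():.2f}, "
          f"range [{preds.min():.2f}, {preds.max():.2f}]")
    obs = series["hospitalizations"]
    print(f"observed:  mean {obs.mean():.2f}, sd {obs.std():.2f}, "
          f"range [{obs.min():.0f}, {obs.max():.0f}]")


if __name__ == "__main__":
    main()
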