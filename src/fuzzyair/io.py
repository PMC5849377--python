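"""CSV and configuration I/O for daily exposure/outcome series."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "read_series_csv",
    "write_series_csv",
    "write_predictions_csv",
    "load_model_config",
    "sha256_file",
    "RunManifest",
]

REQUIRED_EXPOSURES = ["pm10", "no2", "temperature", "wind"]


class SchemaError(ValueError):
    """Raised when an input CSV does not match the expected column schema."""


def read_series_csv(path, require_counts: bool = False) -> pd.DataFrame:
    """Read a daily series CSV (date, pm10, no2, temperature, wind[, hospitalizations]).

    Dates must parse ISO-8601 and be strictly increasing at daily frequency;
    calendar gaps are tolerated but reported. Counts, when present, must be
    non-negative integers (NaN allowed for missing days).
    """
    df = pd.read_csv(path)
    missing = [c for c in ["date", *REQUIRED_EXPOSURES] if c not in df.columns]
    if require_counts and "hospitalizations" not in df.columns:
        missing.append("hospitalizations")
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as err:
        raise SchemaError(f"{path}: unparseable dates: {err}") from err
    deltas = df["date"].diff().dropna()
    if (deltas <= pd.Timedelta(0)).any():
        raise SchemaError(f"{path}: dates must be strictly increasing")
    if "hospitalizations" in df.columns:
        counts = df["hospitalizations"].dropna()
        if (counts < 0).any() or (counts != counts.round()).any():
            raise SchemaError(f"{path}: hospitalization counts must be non-negative integers")
    return df


def write_series_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.3f")


def write_predictions_csv(dates, predictions, path) -> None:
    pd.DataFrame({
        "date": pd.to_datetime(pd.Series(list(dates))).dt.strftime("%Y-%m-%d"),
        "predicted": [f"{p:.3f}" if p == p else "" for p in predictions],
    }).to_csv(path, index=False)


def load_model_config(path) -> dict:
    """Load breakpoint/domain overrides from a YAML (or JSON) file."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: model config must be a mapping")
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest:
    """Provenance record for one pipeline run.

    Identical fields (timestamp aside) imply identical outputs, because every
    stage is deterministic given config, inputs and seed.
    """

    def __init__(self, subcommand: str, seed=None, config_path=None, input_path=None):
        from datetime import datetime, timezone
        from importlib.metadata import version, PackageNotFoundError

        try:
            pkg_version = version("fuzzyair")
        except PackageNotFoundError:  # running from a source tree
            pkg_version = "unknown"
        self.fields = {
            "subcommand": subcommand,
            "seed": seed,
            "config_sha256": sha256_file(config_path) if config_path else None,
            "input_sha256": sha256_file(input_path) if input_path else None,
            "package_version": pkg_version,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.fields, indent=2) + "\n")
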