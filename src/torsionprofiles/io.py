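"""File round-trips for histograms, fit parameters, angle samples and
comparison reports.

All outputs are plain text (CSV / JSON) and deterministic: JSON keys are
sorted and no timestamps are written, so re-running a pipeline with the
same inputs and configuration reproduces files byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import AngleSample
from .extraction import TorsionHistogram
from .fitting import FitParameters


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_histogram(hist: TorsionHistogram, path: str | Path, config: dict | None = None) -> None:
    """Write counts as CSV (bin_start_deg, bin_end_deg, count) plus a JSON
    sidecar carrying the histogram metadata and the producing config."""
    path = Path(path)
    edges = hist.bin_edges
    df = pd.DataFrame({
        "bin_start_deg": edges[:-1],
        "bin_end_deg": edges[1:],
        "count": hist.counts,
    })
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "pattern_id": hist.pattern_id,
        "environment": hist.environment,
        "n_samples": hist.n_samples,
        "n_bins": hist.n_bins,
        "augmented": bool(hist.augmented),
    }
    if config is not None:
        meta["config"] = config
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_histogram(path: str | Path) -> TorsionHistogram:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text(encoding="utf-8"))
    counts = df["count"].to_numpy(dtype=np.int64)
    return TorsionHistogram(meta["pattern_id"], meta["environment"], counts, meta["augmented"])


def write_fit_parameters(
    fits: list[dict],
    path: str | Path,
    config: dict | None = None,
) -> None:
    """Write a JSON array of fit records.

    Each record: ``{pattern_id, environment, triplets: [{a, b_deg, c_deg}],
    overlap_scaled, residual, n_samples}``.  Build records with
    :func:`fit_record`.
    """
    doc: dict = {"fits": fits}
    if config is not None:
        doc["config"] = config
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def fit_record(params: FitParameters, pattern_id: str, environment: str, n_samples: int) -> dict:
    return {
        "pattern_id": pattern_id,
        "environment": environment,
        "triplets": [
            {"a": a, "b_deg": float(np.degrees(b)), "c_deg": float(np.degrees(c))}
            for a, b, c in params.triplets
        ],
        "overlap_scaled": bool(params.overlap_scaled),
        "residual": params.residual,
        "n_samples": int(n_samples),
    }


def read_fit_parameters(path: str | Path) -> list[tuple[FitParameters, dict]]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for rec in doc["fits"]:
        triplets = [
            (t["a"], float(np.radians(t["b_deg"])), float(np.radians(t["c_deg"])))
            for t in rec["triplets"]
        ]
        params = FitParameters(triplets, rec["overlap_scaled"], residual=rec.get("residual"))
        out.append((params, rec))
    return out


def write_angle_sample(sample: AngleSample, path: str | Path) -> None:
    doc = {
        "pattern_id": sample.pattern_id,
        "environment": sample.environment,
        "angles_deg": [round(float(a), 6) for a in sample.angles],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n", encoding="utf-8")


def read_angle_sample(path: str | Path) -> AngleSample:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return AngleSample(np.asarray(doc["angles_deg"], dtype=float),
                       doc["environment"], doc["pattern_id"])


def write_comparison(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.6f")


def write_cdfs(cdfs: dict, path: str | Path) -> None:
    """Flatten per-pair metric CDF supports into a long-format CSV."""
    rows = []
    for (env_a, env_b), metrics in sorted(cdfs.items()):
        for metric, values in sorted(metrics.items()):
            for i, v in enumerate(np.sort(values)):
                rows.append({
                    "env_a": env_a, "env_b": env_b, "metric": metric,
                    "value": float(v), "cdf": (i + 1) / len(values),
                })
    pd.DataFrame(rows, columns=["env_a", "env_b", "metric", "value", "cdf"]).to_csv(
        Path(path), index=False, float_format="%.6f")
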