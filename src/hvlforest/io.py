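"""CSV / YAML / JSON readers and writers for the pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cv import CvConfig
from .errors import InputError
from .metrics import EvalReport

__all__ = [
    "read_feature_table",
    "load_cv_config",
    "write_eval_report",
    "plot_confidence_curves",
]


def read_feature_table(
    path,
    output_col: str = "y",
    id_col: str | None = None,
    drop_cols: tuple[str, ...] = ("in_cliff",),
):
    """Read a feature CSV into (X, y, ids), preserving row order.

    All columns other than the output, the optional ID column, and any
    ``drop_cols`` sidecars (e.g. the generator's ``in_cliff`` marker)
    are treated as numeric features.
    """
    frame = pd.read_csv(path)
    if output_col not in frame.columns:
        raise InputError(f"output column {output_col!r} not in {path}")
    y = frame[output_col].to_numpy(dtype=float)
    ids = frame[id_col] if id_col is not None and id_col in frame.columns else None
    skip = {output_col} | ({id_col} if id_col else set()) | set(drop_cols)
    feats = frame[[c for c in frame.columns if c not in skip]]
    non_numeric = feats.select_dtypes(exclude=[np.number]).columns.tolist()
    if non_numeric:
        raise InputError(f"non-numeric feature columns: {non_numeric}")
    return feats.to_numpy(dtype=float), y, ids


def load_cv_config(path) -> CvConfig:
    """Build a CvConfig from a YAML mapping of field names to values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InputError(f"config file {path} must contain a mapping")
    valid = set(CvConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise InputError(f"unknown config keys: {sorted(unknown)}")
    return CvConfig(**raw)


def write_eval_report(report: EvalReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def plot_confidence_curves(curves, out_path, normalize: bool = True) -> None:
    """Plot curves (iterable of ConfidenceCurve) to an image file.

    With ``normalize`` every curve is divided by its MSE0 so datasets of
    different error scale share a y-axis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        yvals = curve.mse_at_k / curve.mse0 if normalize else curve.mse_at_k
        frac_removed = np.arange(curve.n) / curve.n
        ax.plot(frac_removed, yvals, label=curve.label)
    ax.set_xlabel("fraction of predictions removed")
    ax.set_ylabel("MSE / MSE0" if normalize else "MSE")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
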