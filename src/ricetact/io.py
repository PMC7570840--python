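"""Plain-text file formats: TXT signals, CSV manifests and feature tables.

Signals are stored the way the acquisition software stores them — one
decimal voltage per line in a TXT file — with a CSV manifest binding
signal ids, class labels and file paths.  Feature tables are CSV with a
``{letter}_{name}`` column per feature (e.g. ``b_variance``) at full
double precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .signals import LabeledDataset, TactileSignal

__all__ = [
    "read_signal_txt",
    "write_signal_txt",
    "write_dataset",
    "load_dataset",
    "write_feature_table",
    "read_feature_table",
]


def read_signal_txt(path) -> np.ndarray:
    """Read one voltage per line; trailing blank lines are ignored.

    The class label lives in the manifest, not in the signal file, so
    this returns the raw sample array.
    """
    samples: List[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                samples.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {text!r} at line {lineno}"
                ) from None
    if not samples:
        raise ValueError(f"{path}: empty signal file")
    return np.asarray(samples, dtype=float)


def write_signal_txt(samples, path) -> None:
    """Write one voltage per line with round-trip-exact precision."""
    x = np.asarray(samples, dtype=float)
    with open(path, "w") as fh:
        for value in x:
            fh.write(f"{float(value)!r}\n")


def write_dataset(dataset: LabeledDataset, out_dir) -> Path:
    """Write every signal as TXT plus a ``manifest.csv``; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sig in dataset.signals:
        rel = f"{sig.signal_id}.txt"
        write_signal_txt(sig.samples, out / rel)
        rows.append((sig.signal_id, sig.class_label, rel))
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=["signal_id", "class_label", "path"]).to_csv(
        manifest, index=False
    )
    return manifest


def load_dataset(manifest_path) -> LabeledDataset:
    """Read a manifest CSV and the signal files it points to."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    base = manifest_path.parent
    signals = []
    for row in table.itertuples(index=False):
        samples = read_signal_txt(base / row.path)
        signals.append(
            TactileSignal(
                samples=samples,
                class_label=str(row.class_label),
                signal_id=str(row.signal_id),
            )
        )
    return LabeledDataset(signals=signals)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table CSV at full double precision."""
    expected = ["signal_id", "class_label", *FEATURE_COLUMNS]
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    table[expected].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
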