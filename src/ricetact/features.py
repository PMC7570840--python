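"""The 13 tactile-signal features.

Five dimensional statistics (mean, variance, standard deviation, RMS,
peak-to-peak), six dimensionless shape statistics (kurtosis, skewness,
waveform / pulse / peak / margin factors) and two fractal descriptors
(box-counting dimension of the signal graph and the rescaled-range Hurst
exponent).  In tables and reports the features carry the letters a–m.

Conventions
-----------
* Variance and standard deviation use the population (1/n) form.
* Kurtosis is the plain (non-excess) biased fourth standardised moment,
  so Gaussian noise gives ≈ 3; skewness is the biased third moment.
* The amplitude numerator of the pulse, peak and margin factors is the
  peak-to-peak value by default: these signals are near-constant and
  positive, so max(x)/μ would be pinned at ≈ 1 and carry no shape
  information, while PK/μ resolves the slip activity.  ``peak_mode="max"``
  switches to the literal maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .signals import LabeledDataset, TactileSignal

__all__ = [
    "FEATURE_LETTERS",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "FEATURE_GROUPS",
    "FeatureVector",
    "DimensionalFeatures",
    "DimensionlessFeatures",
    "dimensional_features",
    "dimensionless_features",
    "box_dimension",
    "hurst_exponent",
    "extract_features",
    "extract_feature_table",
]

FEATURE_LETTERS = "abcdefghijklm"

FEATURE_NAMES = (
    "mean_value",
    "variance",
    "standard_deviation",
    "root_mean_square",
    "peak_to_peak",
    "kurtosis",
    "skewness",
    "waveform_factor",
    "pulse_factor",
    "peak_factor",
    "margin_factor",
    "box_dimension",
    "hurst_exponent",
)

#: Column names used in feature tables, e.g. ``b_variance``.
FEATURE_COLUMNS = tuple(
    f"{letter}_{name}" for letter, name in zip(FEATURE_LETTERS, FEATURE_NAMES)
)

#: The feature groups used to train the classifier: dimensional (I),
#: dimensionless (II), fractal (III) and the GA-selected subset (IV).
FEATURE_GROUPS = {
    "I": "abcde",
    "II": "fghijk",
    "III": "lm",
    "IV": "bfhlm",
}


def _as_samples(signal: Union[TactileSignal, Sequence[float], np.ndarray]) -> np.ndarray:
    if isinstance(signal, TactileSignal):
        return signal.samples
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    return x


class DimensionalFeatures(NamedTuple):
    mean_value: float
    variance: float
    standard_deviation: float
    root_mean_square: float
    peak_to_peak: float


class DimensionlessFeatures(NamedTuple):
    kurtosis: float
    skewness: float
    waveform_factor: float
    pulse_factor: float
    peak_factor: float
    margin_factor: float


@dataclass(frozen=True)
class FeatureVector:
    """The 13 named features of one signal (letters a–m)."""

    mean_value: float
    variance: float
    standard_deviation: float
    root_mean_square: float
    peak_to_peak: float
    kurtosis: float
    skewness: float
    waveform_factor: float
    pulse_factor: float
    peak_factor: float
    margin_factor: float
    box_dimension: float
    hurst_exponent: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def __getitem__(self, letter: str) -> float:
        idx = FEATURE_LETTERS.index(letter)
        return getattr(self, FEATURE_NAMES[idx])


def dimensional_features(signal) -> DimensionalFeatures:
    """Mean, population variance / standard deviation, RMS, peak-to-peak."""
    x = _as_samples(signal)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mean = float(np.mean(x))
    std = float(np.sqrt(np.mean((x - mean) ** 2)))
    variance = std * std  # exact b = c² identity
    rms = float(np.sqrt(np.mean(x**2)))
    ptp = float(np.max(x) - np.min(x))
    return DimensionalFeatures(mean, variance, std, rms, ptp)


def dimensionless_features(signal, peak_mode: str = "ptp") -> DimensionlessFeatures:
    """Kurtosis, skewness and the four amplitude-normalised shape factors.

    Raises :class:`ValueError` on a zero-mean or zero-RMS signal, for
    which the normalised factors are undefined.
    """
    if peak_mode not in ("ptp", "max"):
        raise ValueError("peak_mode must be 'ptp' or 'max'")
    x = _as_samples(signal)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mean, _, std, rms, ptp = dimensional_features(x)
    if mean == 0.0:
        raise ValueError("mean-normalised factors undefined for zero-mean signal")
    if rms == 0.0:
        raise ValueError("RMS-normalised factors undefined for zero-RMS signal")
    if std == 0.0:
        # Constant signal: standardised moments are taken as their
        # symmetric-distribution limits.
        kurt, skew = 0.0, 0.0
    else:
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        skew = float(stats.skew(x, bias=True))
    peak = ptp if peak_mode == "ptp" else float(np.max(x))
    clearance_base = float(np.mean(np.sqrt(np.abs(x)))) ** 2
    return DimensionlessFeatures(
        kurtosis=kurt,
        skewness=skew,
        waveform_factor=rms / abs(mean),
        pulse_factor=peak / abs(mean),
        peak_factor=peak / rms,
        margin_factor=peak / clearance_base,
    )


# ---------------------------------------------------------------------------
# Fractal descriptors
# ---------------------------------------------------------------------------

def _default_box_scales() -> np.ndarray:
    return 2.0 ** -np.arange(2, 8)


def box_dimension(signal, scales: Optional[Sequence[float]] = None) -> float:
    """Box-counting (Minkowski–Bouligand) dimension of the signal graph.

    The graph ``{(t_i, x_i)}`` is normalised to the unit square and, for
    each box size δ, the occupied δ-boxes are counted column-wise: within
    each time column of width δ the number of boxes is ``ceil(span/δ)``
    where span is the vertical extent of the samples falling in that
    column (at least one box per non-empty column).  The dimension is the
    least-squares slope of ``ln N(δ)`` against ``ln(1/δ)``.

    A smooth curve gives ≈ 1; the graph of fractional Brownian motion of
    Hurst index H gives ≈ 2 − H.
    """
    x = _as_samples(signal)
    n = x.size
    if n < 64:
        raise ValueError("box dimension needs at least 64 samples")
    deltas = _default_box_scales() if scales is None else np.asarray(scales, float)
    deltas = np.unique(deltas[(deltas > 0) & (deltas < 1)])[::-1]
    if deltas.size < 4 or np.log2(deltas.max() / deltas.min()) < 2:
        raise ValueError("need at least 4 box scales spanning 2 octaves")
    span = np.max(x) - np.min(x)
    xn = (x - np.min(x)) / span if span > 0 else np.zeros_like(x)
    t = np.arange(n) / (n - 1)
    log_counts = []
    for delta in deltas:
        cols = np.minimum((t / delta).astype(int), int(np.ceil(1 / delta)) - 1)
        order = np.argsort(cols, kind="stable")
        sorted_cols = cols[order]
        boundaries = np.flatnonzero(np.diff(sorted_cols)) + 1
        count = 0
        for chunk in np.split(xn[order], boundaries):
            col_span = chunk.max() - chunk.min()
            count += max(1, int(np.ceil(col_span / delta)))
        log_counts.append(np.log(count))
    slope = np.polyfit(np.log(1.0 / deltas), log_counts, 1)[0]
    return float(slope)


def _default_rs_windows(n: int) -> List[int]:
    windows = []
    w = 8
    while w <= n // 4:
        windows.append(w)
        w *= 2
    while len(windows) < 4 and (windows[-1] * 2 if windows else 8) <= n // 2:
        windows.append(windows[-1] * 2 if windows else 8)
    return windows


def hurst_exponent(signal, window_sizes: Optional[Sequence[int]] = None) -> float:
    """Rescaled-range (R/S) estimate of the Hurst exponent.

    For each window size N the series is split into ⌊n/N⌋ blocks; per
    block, R is the range of the mean-adjusted cumulative sum and S the
    population standard deviation, and R/S is averaged over blocks
    (blocks with S = 0 are skipped).  The estimate is the least-squares
    slope of log10(R/S) on log10(N).  White noise gives ≈ 0.5; strongly
    persistent signals can exceed 1 because the slope is a finite-sample
    regression, not a constrained index.
    """
    x = _as_samples(signal)
    n = x.size
    if n < 64:
        raise ValueError("R/S estimation needs at least 64 samples")
    windows = _default_rs_windows(n) if window_sizes is None else sorted(
        int(w) for w in window_sizes
    )
    windows = [w for w in windows if 2 <= w <= n // 2]
    log_n, log_rs = [], []
    for w in windows:
        blocks = x[: (n // w) * w].reshape(-1, w)
        means = blocks.mean(axis=1, keepdims=True)
        deviations = blocks - means
        cumulative = np.cumsum(deviations, axis=1)
        r = cumulative.max(axis=1) - cumulative.min(axis=1)
        s = blocks.std(axis=1)
        ok = s > 0
        if not np.any(ok):
            continue
        log_n.append(np.log10(w))
        log_rs.append(np.log10(np.mean(r[ok] / s[ok])))
    if len(log_n) < 4:
        raise ValueError("fewer than 4 usable R/S scales")
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def extract_features(signal, peak_mode: str = "ptp") -> FeatureVector:
    """Compute all 13 features a–m of one signal."""
    x = _as_samples(signal)
    dim = dimensional_features(x)
    dimless = dimensionless_features(x, peak_mode=peak_mode)
    return FeatureVector(
        *dim,
        *dimless,
        box_dimension=box_dimension(x),
        hurst_exponent=hurst_exponent(x),
    )


def extract_feature_table(dataset: LabeledDataset, peak_mode: str = "ptp"):
    """Feature table of a dataset: one row per signal, columns a–m.

    Returns a :class:`pandas.DataFrame` with ``signal_id`` and
    ``class_label`` followed by the 13 feature columns.
    """
    import pandas as pd

    rows = []
    for sig in dataset.signals:
        fv = extract_features(sig, peak_mode=peak_mode)
        rows.append((sig.signal_id, sig.class_label, *fv.to_array()))
    return pd.DataFrame(
        rows, columns=["signal_id", "class_label", *FEATURE_COLUMNS]
    )
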