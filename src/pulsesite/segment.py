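"""Systolic-peak detection and fixed-length, peak-centered period windows.

Treating each cardiac period as an independent sample is the small-data
augmentation device of this pipeline: a window of fixed length is centered
on every detected systolic peak (the moment of maximum systolic flow), so
neighbouring windows overlap whenever the cardiac period is shorter than
the window.  The canonical window length is 1495 samples (~0.897 s at
1666 Hz), the input size the downstream classifier consumes after its
average-pooling stage (1495 = 299 x 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthdata import ARTERY_CLASSES

CANONICAL_WINDOW_LEN = 1495


@dataclass
class PeriodWindow:
    """One fixed-length, peak-centered, labeled signal segment."""

    samples: np.ndarray
    label: str | None
    recording_id: str | None
    center_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


def detect_systolic_peaks(series: np.ndarray, fs: float,
                          min_period_s: float = 0.4,
                          prominence_frac: float = 0.3) -> np.ndarray:
    """Locate systolic peaks in a band-passed pulse signal.

    A peak is a local maximum whose prominence exceeds ``prominence_frac``
    of the series' amplitude range; consecutive peaks are at least
    ``min_period_s`` apart (default 0.4 s, a 150 bpm refractory bound).
    A flat series yields no peaks.
    """
    if min_period_s <= 0:
        raise ValueError("min_period_s must be positive")
    series = np.asarray(series, dtype=float)
    rng = series.max() - series.min()
    if rng == 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(series, distance=max(1, int(round(min_period_s * fs))),
                          prominence=prominence_frac * rng)
    return peaks.astype(int)


def extract_periods(series: np.ndarray, peaks: np.ndarray,
                    window_len: int = CANONICAL_WINDOW_LEN,
                    label: str | None = None,
                    recording_id: str | None = None) -> list[PeriodWindow]:
    """Cut one window of ``window_len`` samples around each interior peak.

    The window spans ``[peak - window_len//2, peak + ceil(window_len/2))``
    so the peak sits at the left-of-center midpoint sample for even
    lengths.  Peaks whose window would cross the series bounds are
    silently dropped; windows may overlap.
    """
    series = np.asarray(series, dtype=float)
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    if window_len > len(series):
        raise ValueError("window_len exceeds series length")
    half_lo = window_len // 2
    half_hi = window_len - half_lo
    out = []
    for pk in np.asarray(peaks, dtype=int):
        lo, hi = pk - half_lo, pk + half_hi
        if lo < 0 or hi > len(series):
            continue
        out.append(PeriodWindow(samples=series[lo:hi], label=label,
                                recording_id=recording_id, center_index=int(pk)))
    return out


def label_periods(windows: list[PeriodWindow], label: str,
                  recording_id: str | None = None) -> list[PeriodWindow]:
    """Attach the acquisition-site label (and source id) to every window."""
    if label not in ARTERY_CLASSES:
        raise ValueError(f"unknown artery class {label!r}")
    for w in windows:
        w.label = label
        if recording_id is not None:
            w.recording_id = recording_id
    return windows


def windows_to_arrays(windows: list[PeriodWindow]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, labels, recording_ids) arrays for training."""
    if not windows:
        raise ValueError("no windows to stack")
    X = np.stack([w.samples for w in windows]).astype(np.float32)
    y = np.array([w.label for w in windows])
    rids = np.array([w.recording_id for w in windows])
    return X, y, rids


def save_windows(windows: list[PeriodWindow], matrix_path, manifest_path) -> None:
    """Serialize windows as a whitespace matrix plus a CSV label manifest."""
    import pandas as pd
    X, y, rids = windows_to_arrays(windows)
    np.savetxt(matrix_path, X, fmt="%.7g")
    pd.DataFrame({"window_id": np.arange(len(windows)), "recording_id": rids,
                  "label": y,
                  "center_index": [w.center_index for w in windows]
                  }).to_csv(manifest_path, index=False)


def load_windows(matrix_path, manifest_path) -> list[PeriodWindow]:
    import pandas as pd
    X = np.atleast_2d(np.loadtxt(matrix_path))
    man = pd.read_csv(manifest_path)
    return [PeriodWindow(samples=X[i], label=row.label,
                         recording_id=row.recording_id,
                         center_index=int(row.center_index))
            for i, row in enumerate(man.itertuples())]
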