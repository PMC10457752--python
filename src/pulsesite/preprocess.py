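"""Signal conditioning and pulse-wave characterization.

Implements the decomposition of a raw impedance channel into its static
baseline Z0 and pulsatile component dZ(t) (and likewise rPPG0 / drPPG(t)
for the optical channel), plus the standard conditioning steps: Savitzky-
Golay smoothing, a zero-phase Butterworth band-pass, and two-step
normalization (mean removal, division by the SD).

The site figure of merit is the sensitivity, the mean per-beat dZ(t)
amplitude as a percentage of the maximum measured impedance:
``sensitivity = 100 * dZ_mean / Z_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, savgol_filter

from .synthdata import Recording

DEFAULT_SIDE_POINTS = 100
DEFAULT_POLY_ORDER = 3


@dataclass
class PulseDecomposition:
    """Baseline / pulsatile split of one channel with per-beat summaries.

    ``delta_mean`` is the mean per-beat peak-to-trough amplitude of the
    pulsatile component and ``delta_sd`` its SD across beats.  For an
    impedance channel ``sensitivity_pct = 100 * delta_mean / raw_max``;
    for the rPPG channel the sensitivity field is computed the same way on
    the voltage scale.
    """

    baseline: float          # Z0 (ohm) or rPPG0 (V): median of the raw channel
    delta: np.ndarray        # dZ(t) or drPPG(t): smoothed channel - baseline
    delta_mean: float
    delta_sd: float
    raw_max: float           # max of the raw channel (Z in the sensitivity ratio)
    per_beat_amplitudes: np.ndarray
    sensitivity_pct: float


def savgol_smooth(series: np.ndarray, side_points: int = DEFAULT_SIDE_POINTS,
                  poly_order: int = DEFAULT_POLY_ORDER) -> np.ndarray:
    """Savitzky-Golay least-squares smoothing with window 2*side_points+1."""
    series = np.asarray(series, dtype=float)
    window = 2 * side_points + 1
    if len(series) <= window:
        raise ValueError(f"series length {len(series)} too short for "
                         f"window {window}")
    if not 0 <= poly_order < window:
        raise ValueError("poly_order must satisfy 0 <= order < window")
    return savgol_filter(series, window, poly_order)


def savgol_coefficients(side_points: int = DEFAULT_SIDE_POINTS,
                        poly_order: int = DEFAULT_POLY_ORDER) -> np.ndarray:
    """Central FIR coefficients of the smoothing filter (for analysis)."""
    from scipy.signal import savgol_coeffs
    return savgol_coeffs(2 * side_points + 1, poly_order)


def bandpass(series: np.ndarray, fs: float, f_lo: float = 0.5,
             f_hi: float = 50.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward application).

    Defaults to the order-2, 0.5-50 Hz design used for pulse-wave
    conditioning; zero-phase filtering keeps systolic-peak times unshifted.
    """
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(f"invalid band [{f_lo}, {f_hi}] for fs={fs}")
    b, a = butter(order, [f_lo, f_hi], btype="bandpass", fs=fs)
    return filtfilt(b, a, np.asarray(series, dtype=float))


def normalize(series: np.ndarray) -> np.ndarray:
    """Two-step normalization: remove the mean, divide by the SD."""
    series = np.asarray(series, dtype=float)
    sd = series.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance input cannot be normalized")
    return (series - series.mean()) / sd


def decompose(channel: np.ndarray, beat_indices: np.ndarray, fs: float,
              side_points: int = DEFAULT_SIDE_POINTS,
              poly_order: int = DEFAULT_POLY_ORDER) -> PulseDecomposition:
    """Split a raw channel into baseline + pulsatile part and summarize beats.

    The baseline is the channel median (robust to the asymmetric pulse
    shape); the pulsatile component is the Savitzky-Golay-smoothed channel
    minus that baseline.  Per-beat amplitude is the max-min of the
    pulsatile component within each beat-centered span (midpoints between
    consecutive systolic peaks bound each span).
    """
    channel = np.asarray(channel, dtype=float)
    beats = np.asarray(beat_indices, dtype=int)
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to summarize amplitudes")

    baseline = float(np.median(channel))
    delta = savgol_smooth(channel, side_points, poly_order) - baseline

    mids = (beats[:-1] + beats[1:]) // 2
    edges = np.concatenate(([max(0, 2 * beats[0] - mids[0])], mids,
                            [min(len(channel), 2 * beats[-1] - mids[-1])]))
    amps = np.array([delta[lo:hi].max() - delta[lo:hi].min()
                     for lo, hi in zip(edges[:-1], edges[1:]) if hi - lo > 1])

    delta_mean = float(amps.mean())
    raw_max = float(channel.max())
    return PulseDecomposition(
        baseline=baseline, delta=delta, delta_mean=delta_mean,
        delta_sd=float(amps.std(ddof=0)), raw_max=raw_max,
        per_beat_amplitudes=amps,
        sensitivity_pct=sensitivity(delta_mean, raw_max),
    )


def sensitivity(delta_mean: float, z_max: float) -> float:
    """Pulse amplitude as a percentage of the maximum measured value."""
    if z_max <= 0:
        raise ValueError("z_max must be positive")
    return 100.0 * delta_mean / z_max


def characterize_recording(rec: Recording, **kw) -> pd.DataFrame:
    """Per-channel decomposition summary rows for one recording.

    Columns mirror the per-site amplitude table layout: site, channel,
    delta_mean, delta_sd, sensitivity_pct.
    """
    rows = []
    for name, series in rec.channels.items():
        d = decompose(series, rec.beat_indices, rec.fs, **kw)
        rows.append({"site": rec.label, "recording_id": rec.recording_id,
                     "channel": name, "delta_mean": d.delta_mean,
                     "delta_sd": d.delta_sd,
                     "sensitivity_pct": d.sensitivity_pct})
    return pd.DataFrame(rows)


def sensitivity_table(recordings) -> pd.DataFrame:
    """Across-recording amplitude/sensitivity summary, one row per site x channel."""
    per_rec = pd.concat([characterize_recording(r) for r in recordings],
                        ignore_index=True)
    return (per_rec.groupby(["site", "channel"], as_index=False)
            .agg(delta_mean=("delta_mean", "mean"),
                 delta_sd=("delta_sd", "mean"),
                 sensitivity_pct=("sensitivity_pct", "mean")))
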