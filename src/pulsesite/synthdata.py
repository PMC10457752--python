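"""Synthetic generation of labeled peripheral-artery EBI + rPPG recordings.

Real joint electrical-bioimpedance (EBI) / reflectance-photoplethysmography
(rPPG) recordings of named peripheral arteries are not publicly available,
so this module emulates their statistical structure: an artery-specific
pulse morphology (systolic peak, dicrotic notch, reflected wave) repeated
with beat-to-beat period jitter, respiratory amplitude modulation, slow
baseline drift and additive sensor noise, riding on a static baseline.

Each impedance channel obeys ``Z(t) = Z0 + dZ(t)`` and the optical channel
``rPPG(t) = rPPG0 + drPPG(t)`` by construction; the generator records the
ground-truth systolic-peak indices so downstream peak detection can be
scored exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ARTERY_CLASSES = ("A", "B", "C", "D", "E")
"""Acquisition sites: brachial (A), carotid (B), radial (C),
posterior tibial (D), ulnar (E)."""

EXCITATION_FREQS = ("50k", "100k", "500k", "1000k")
"""Bioimpedance excitation-frequency labels, kHz."""

CHANNEL_NAMES = tuple(f"z_{f}" for f in EXCITATION_FREQS) + ("rppg",)

_DRIFT_FREQ_HZ = 0.05  # very-low-frequency baseline wander


@dataclass(frozen=True)
class Morphology:
    """Dimensionless shape parameters of one pulse period.

    All values are fractions of the cardiac period (widths, delays) or of
    the systolic amplitude (wave heights).
    """

    systolic_width_frac: float = 0.14
    notch_delay_frac: float = 0.28
    notch_amp_frac: float = 0.15
    reflected_amp_frac: float = 0.30

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"morphology fraction {name}={v} outside [0, 1]")
        if self.systolic_width_frac == 0.0:
            raise ValueError("systolic_width_frac must be > 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of one labeled synthetic recording."""

    artery_class: str
    fs: float = 1666.0
    duration: float = 60.0
    heart_rate_mean: float = 65.0
    heart_rate_sd: float = 2.0
    z0: float = 100.0
    delta_z_amp: float = 0.3
    rppg0: float = 1.5
    delta_rppg_amp: float = 0.3
    morphology: Morphology = field(default_factory=Morphology)
    resp_rate: float = 15.0
    resp_mod_depth: float = 0.05
    drift_amp: float = 0.05
    noise_sd: float = 0.01
    rppg_drift_amp: float = 0.005
    rppg_noise_sd: float = 0.003
    excitation_freqs: Sequence[str] = EXCITATION_FREQS
    freq_scale: Mapping[str, float] = field(
        default_factory=lambda: {"50k": 0.85, "100k": 1.0, "500k": 1.15, "1000k": 1.25}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.heart_rate_mean <= 0:
            raise ValueError("heart_rate_mean must be positive")
        for name in ("delta_z_amp", "delta_rppg_amp", "heart_rate_sd",
                     "resp_mod_depth", "drift_amp", "noise_sd",
                     "rppg_drift_amp", "rppg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.artery_class not in ARTERY_CLASSES:
            raise ValueError(f"unknown artery class {self.artery_class!r}")
        self.morphology.validate()
        if self.duration < 60.0 / self.heart_rate_mean:
            raise ValueError("duration shorter than one cardiac period")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excitation_freqs"] = list(self.excitation_freqs)
        d["freq_scale"] = dict(self.freq_scale)
        return d


@dataclass
class Recording:
    """A multichannel labeled time series at fixed sample rate.

    ``channels`` maps ``z_<freq>`` names to impedance series in ohms plus
    one ``rppg`` series in volts; all series have equal length.
    ``beat_indices`` holds ground-truth systolic-peak sample indices
    (available because the recording is synthetic).
    """

    fs: float
    label: str
    channels: dict[str, np.ndarray]
    beat_indices: np.ndarray
    recording_id: str
    config: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        bi = np.asarray(self.beat_indices)
        if bi.size and (np.any(np.diff(bi) <= 0) or bi[0] < 0
                        or bi[-1] >= lengths.pop()):
            raise ValueError("beat_indices must be strictly increasing and in bounds")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def pulse_template(morphology: Morphology, period_samples: int,
                   amplitude: float) -> np.ndarray:
    """One cardiac-period waveform as a superposition of smooth bumps.

    The systolic peak is a Gaussian bump at the segment midpoint.  The
    dicrotic complex — a notch dip followed by a reflected-wave bump — is a
    single unit whose overall depth scales with ``notch_amp_frac``: with no
    notch the reflected wave merges into the systolic decay and the segment
    has exactly one local maximum, as in an overdamped pulse.

    Returns a segment of length ``period_samples`` whose global maximum sits
    at the midpoint sample and whose peak-to-trough range equals
    ``amplitude`` exactly (the segment minimum is 0).
    """
    if period_samples < 8:
        raise ValueError("period_samples must be >= 8")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0.0:
        return np.zeros(period_samples)
    morphology.validate()

    mid = period_samples // 2
    x = (np.arange(period_samples) - mid) / period_samples  # in (-0.5, 0.5]
    m = morphology
    ws = 0.5 * m.systolic_width_frac
    sys_bump = np.exp(-0.5 * (x / ws) ** 2)
    # dicrotic complex: dip just before the reflected bump, both after systole
    c_notch = 0.55 * m.notch_delay_frac
    c_refl = m.notch_delay_frac
    dip = np.exp(-0.5 * ((x - c_notch) / (0.45 * ws)) ** 2)
    refl = np.exp(-0.5 * ((x - c_refl) / (1.3 * ws)) ** 2)
    dicrotic = m.notch_amp_frac * (m.reflected_amp_frac * refl - 0.5 * dip)

    # keep the systolic peak the strict global maximum: scale the dicrotic
    # complex down just enough that sys + gamma*dicrotic < peak off-center
    rel = dicrotic - dicrotic[mid]
    rising = np.flatnonzero(rel > 0)
    rising = rising[rising != mid]
    if rising.size:
        gamma = min(1.0, 0.95 * np.min((1.0 - sys_bump[rising])
                                       / rel[rising]))
    else:
        gamma = 1.0
    shape = sys_bump + gamma * dicrotic

    shape = shape - shape.min()
    return amplitude * shape / shape[mid]


def _beat_schedule(cfg: SyntheticConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat period lengths (samples) and systolic-peak indices."""
    n = int(round(cfg.fs * cfg.duration))
    mean_period = cfg.fs * 60.0 / cfg.heart_rate_mean
    sd_period = cfg.fs * 60.0 * cfg.heart_rate_sd / cfg.heart_rate_mean**2
    periods, peaks = [], []
    start = 0.0
    while True:
        p = mean_period if sd_period == 0 else rng.normal(mean_period, sd_period)
        p = int(round(max(p, 0.25 * mean_period, 8)))
        if start + p > n:
            break
        periods.append(p)
        peaks.append(int(start) + p // 2)
        start += p
    return np.asarray(periods, dtype=int), np.asarray(peaks, dtype=int)


def _pulse_train(cfg: SyntheticConfig, amplitude: float, periods: np.ndarray,
                 peaks: np.ndarray, n: int) -> np.ndarray:
    """Concatenated per-beat templates with respiratory amplitude modulation."""
    out = np.zeros(n)
    resp_omega = 2.0 * np.pi * cfg.resp_rate / 60.0
    start = 0
    for p, pk in zip(periods, peaks):
        resp = 1.0 + cfg.resp_mod_depth * np.sin(resp_omega * pk / cfg.fs)
        out[start:start + p] = pulse_template(cfg.morphology, p, amplitude * resp)
        start += p
    return out


def generate_recording(config: SyntheticConfig, recording_id: str = "rec0",
                       return_components: bool = False):
    """Generate one labeled multichannel recording from its configuration.

    Every impedance channel is ``z0 + drift + resp-modulated pulse train +
    noise`` with a per-excitation-frequency amplitude factor and independent
    noise; the rPPG channel is built the same way around ``rppg0``.  The
    same seed yields a bit-identical recording.

    With ``return_components=True`` also returns the noise-free programmed
    parts ``{channel: (baseline+drift, pulse_train)}`` for verification.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs

    periods, peaks = _beat_schedule(config, rng)
    if len(peaks) == 0:
        raise ValueError("duration too short to fit one cardiac period")

    z_train = _pulse_train(config, config.delta_z_amp, periods, peaks, n)
    r_train = _pulse_train(config, config.delta_rppg_amp, periods, peaks, n)

    channels: dict[str, np.ndarray] = {}
    components: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for f in config.excitation_freqs:
        scale = float(config.freq_scale.get(f, 1.0))
        phase = rng.uniform(0, 2 * np.pi)
        drift = config.drift_amp * np.sin(2 * np.pi * _DRIFT_FREQ_HZ * t + phase)
        noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else 0.0
        pulse = scale * z_train
        channels[f"z_{f}"] = config.z0 + drift + pulse + noise
        components[f"z_{f}"] = (config.z0 + drift, pulse)

    phase = rng.uniform(0, 2 * np.pi)
    drift = config.rppg_drift_amp * np.sin(2 * np.pi * _DRIFT_FREQ_HZ * t + phase)
    noise = (rng.normal(0.0, config.rppg_noise_sd, n)
             if config.rppg_noise_sd else 0.0)
    channels["rppg"] = config.rppg0 + drift + r_train + noise
    components["rppg"] = (config.rppg0 + drift, r_train)

    rec = Recording(fs=config.fs, label=config.artery_class, channels=channels,
                    beat_indices=peaks, recording_id=recording_id, config=config)
    if return_components:
        return rec, components
    return rec


# ---------------------------------------------------------------------------
# Study-condition defaults: one configuration per acquisition site.
#
# Pulse amplitudes follow the measured per-site means (dZ in ohms, drPPG in
# volts); baselines are set so the impedance sensitivity (100*dZ/Zmax) lands
# on the reported scale — carotid ~0.86%, posterior tibial ~0.27%, the rest
# below.  Respiratory modulation is deeper for the brachial and carotid
# sites, where it is visible in practice.  Morphologies are distinct per
# site; EBI channels are noisier than the optically clean rPPG channel.
# ---------------------------------------------------------------------------

_SITE_DEFAULTS: dict[str, dict] = {
    #        dZ amp   drPPG   z0      morphology (ws, nd, na, ra)     resp
    "A": dict(dz=0.029, dr=0.068, z0=150.0,
              morph=(0.17, 0.30, 0.10, 0.20), resp=0.15),
    "B": dict(dz=11.123, dr=0.225, z0=1282.3,
              morph=(0.10, 0.22, 0.35, 0.50), resp=0.15),
    "C": dict(dz=0.085, dr=0.216, z0=45.0,
              morph=(0.14, 0.30, 0.22, 0.38), resp=0.05),
    "D": dict(dz=0.304, dr=0.413, z0=112.3,
              morph=(0.12, 0.26, 0.06, 0.14), resp=0.05),
    "E": dict(dz=0.167, dr=0.158, z0=80.0,
              morph=(0.19, 0.35, 0.28, 0.30), resp=0.05),
}

EBI_REL_NOISE = 0.06    # noise SD as a fraction of pulse amplitude (EBI)
RPPG_REL_NOISE = 0.01   # rPPG sensor is comparatively clean


def default_config(artery_class: str, seed: int = 0, duration: float = 60.0,
                   null_mode: bool = False, **overrides) -> SyntheticConfig:
    """Study-condition configuration for one acquisition site.

    ``null_mode`` gives every site the same (class-A) morphology and
    amplitudes so that the classes are indistinguishable by construction —
    the negative control for the classifier.
    """
    if artery_class not in ARTERY_CLASSES:
        raise ValueError(f"unknown artery class {artery_class!r}")
    d = _SITE_DEFAULTS["A" if null_mode else artery_class]
    ws, nd, na, ra = d["morph"]
    base = dict(
        artery_class=artery_class,
        duration=duration,
        z0=d["z0"],
        delta_z_amp=d["dz"],
        delta_rppg_amp=d["dr"],
        morphology=Morphology(ws, nd, na, ra),
        resp_mod_depth=d["resp"],
        drift_amp=0.15 * d["dz"],
        noise_sd=EBI_REL_NOISE * d["dz"],
        rppg_drift_amp=0.15 * d["dr"],
        rppg_noise_sd=RPPG_REL_NOISE * d["dr"],
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def _derive_seed(master_seed: int, *parts) -> int:
    h = hashlib.sha256(("/".join(map(str, parts)) + f"#{master_seed}").encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def make_dataset(per_class_configs: Mapping[str, SyntheticConfig] | None = None,
                 n_recordings_per_class: int = 3, seed: int = 0,
                 duration: float = 60.0, null_mode: bool = False
                 ) -> list[Recording]:
    """Balanced labeled dataset: ``n`` recordings for each of the 5 sites.

    Default n=3 mirrors the three consecutive measurements per site.
    Recording seeds are derived deterministically from the master seed so
    two calls with the same seed return identical datasets.
    """
    if per_class_configs is None:
        per_class_configs = {c: default_config(c, duration=duration,
                                               null_mode=null_mode)
                             for c in ARTERY_CLASSES}
    missing = set(ARTERY_CLASSES) - set(per_class_configs)
    if missing:
        raise ValueError(f"missing configs for classes {sorted(missing)}")
    recs: list[Recording] = []
    for c in ARTERY_CLASSES:
        cfg = per_class_configs[c]
        for i in range(n_recordings_per_class):
            rec_seed = _derive_seed(seed, c, i)
            rec_cfg = SyntheticConfig(**{**cfg.to_dict(),
                                         "morphology": cfg.morphology,
                                         "seed": rec_seed})
            recs.append(generate_recording(rec_cfg, recording_id=f"{c}{i}"))
    return recs


def save_recording(rec: Recording, csv_path: str | Path) -> None:
    """Write a recording as CSV plus a JSON sidecar with its metadata."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time_s": rec.time})
    for name in CHANNEL_NAMES:
        if name in rec.channels:
            df[name] = rec.channels[name]
    df.to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "label": rec.label,
        "fs": rec.fs,
        "recording_id": rec.recording_id,
        "beat_indices": rec.beat_indices.tolist(),
        "config": rec.config.to_dict() if rec.config else None,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(csv_path: str | Path) -> Recording:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    channels = {c: df[c].to_numpy() for c in df.columns if c != "time_s"}
    return Recording(fs=meta["fs"], label=meta["label"], channels=channels,
                     beat_indices=np.asarray(meta["beat_indices"], dtype=int),
                     recording_id=meta["recording_id"])
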