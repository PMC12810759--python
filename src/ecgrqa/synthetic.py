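"""Seeded generators for validation signals and quasi-ECG records.

Two families of fixtures:

* canonical dynamical-system signals (sine, Lorenz-x, logistic map, white
  noise) with known embedding/recurrence behaviour, used to validate the
  phase-space and RQA machinery;
* multi-channel quasi-ECG records built from a sum-of-Gaussians beat
  template (P, Q, R, S, T waves) repeated at jittered beat intervals, with
  class-specific morphology so the five study classes are separable in
  recurrence-plot space: dysrhythmia (DR) has strongly irregular beat
  intervals, bundle branch block (BBB) a widened/notched QRS, myocardial
  infarction (MI) an ST-segment shift with deepened Q and inverted T,
  cardiomyopathy (CM) attenuated amplitudes, healthy control (HC) a regular
  narrow-complex rhythm.  Channels are fixed linear mixtures of the beat
  source plus independent channel noise, emulating lead redundancy.

Every generator is a pure function of its spec: the seed fully determines
the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io_ecg import CLASSES, ECGRecord, PTB_CHANNELS


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a canonical test signal."""

    kind: str  # sine | lorenz | logistic_map | white_noise
    fs: float = 250.0
    duration: float = 4.0
    seed: int = 0
    params: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration * self.fs < 100:
            raise ValueError("need at least 100 samples")


@dataclass(frozen=True)
class ECGClassProfile:
    """Morphology parameters of one diagnostic class.

    Wave amplitudes in millivolts, centres/widths in seconds relative to
    the R peak.  ``rr_jitter`` is the coefficient of variation of the beat
    interval; ``qrs_width_mult`` scales the Q/R/S widths; ``st_offset``
    shifts the ST segment; ``amplitude_scale`` scales the whole template.
    """

    label: str
    rr_mean: float = 0.8
    rr_jitter: float = 0.02
    qrs_width_mult: float = 1.0
    st_offset: float = 0.0
    amplitude_scale: float = 1.0
    q_amp: float = -0.1
    t_amp: float = 0.35
    r_prime: float = 0.0  # amplitude of a notch wave after R (BBB)

    def __post_init__(self) -> None:
        if self.rr_mean <= 0 or self.qrs_width_mult <= 0:
            raise ValueError("intervals and widths must be positive")


#: Default class morphologies.  The discriminating parameters satisfy the
#: separability contract: DR interval CV > 0.15 vs HC < 0.05; BBB QRS width
#: >= 1.5x HC; MI ST offset nonzero; CM amplitude <= 0.6x HC.
CLASS_PROFILES: Dict[str, ECGClassProfile] = {
    "HC": ECGClassProfile("HC"),
    "MI": ECGClassProfile("MI", rr_jitter=0.03, st_offset=0.25,
                          q_amp=-0.3, t_amp=-0.2),
    "BBB": ECGClassProfile("BBB", rr_jitter=0.03, qrs_width_mult=2.0,
                           r_prime=0.6),
    "CM": ECGClassProfile("CM", rr_jitter=0.04, qrs_width_mult=1.2,
                          amplitude_scale=0.5),
    "DR": ECGClassProfile("DR", rr_jitter=0.25),
}

# (name, amplitude mV, centre s, width s); Q/R/S widths get qrs_width_mult.
_WAVES = (
    ("P", 0.15, -0.20, 0.040),
    ("Q", -0.10, -0.048, 0.012),
    ("R", 1.00, 0.0, 0.018),
    ("S", -0.25, 0.045, 0.014),
    ("T", 0.35, 0.30, 0.060),
)


def gen_signal(spec: SynthSpec) -> np.ndarray:
    """Generate one canonical 1-D signal, deterministic per seed."""
    n = int(round(spec.duration * spec.fs))
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.kind == "sine":
        period = p.get("period", 1.0)  # seconds
        t = np.arange(n) / spec.fs
        return np.sin(2 * np.pi * t / period + p.get("phase", 0.0))
    if spec.kind == "white_noise":
        return rng.normal(0.0, p.get("sigma", 1.0), size=n)
    if spec.kind == "logistic_map":
        r = p.get("r", 4.0)
        x = p.get("x0", float(rng.uniform(0.1, 0.9)))
        out = np.empty(n)
        for i in range(n):
            x = r * x * (1.0 - x)
            out[i] = x
        return out
    if spec.kind == "lorenz":
        return _lorenz_x(n, dt=p.get("dt", 0.02),
                         sigma=p.get("sigma", 10.0), rho=p.get("rho", 28.0),
                         beta=p.get("beta", 8.0 / 3.0),
                         transient=int(p.get("transient", 500)))
    raise ValueError(f"unknown signal kind {spec.kind!r}")


def _lorenz_x(n: int, dt: float, sigma: float, rho: float, beta: float,
              transient: int) -> np.ndarray:
    """x-component of the Lorenz system, fixed-step RK4."""
    state = np.array([1.0, 1.0, 1.0])

    def deriv(v: np.ndarray) -> np.ndarray:
        x, y, z = v
        return np.array([sigma * (y - x), x * (rho - z) - y,
                         x * y - beta * z])

    out = np.empty(n)
    for i in range(n + transient):
        k1 = deriv(state)
        k2 = deriv(state + dt / 2 * k1)
        k3 = deriv(state + dt / 2 * k2)
        k4 = deriv(state + dt * k3)
        state = state + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i >= transient:
            out[i - transient] = state[0]
    return out


def beat_template(profile: ECGClassProfile, fs: float,
                  span: float = 0.45) -> np.ndarray:
    """One noiseless beat (sum of Gaussian waves) sampled at ``fs``."""
    t = np.arange(-span, span, 1.0 / fs)
    y = np.zeros_like(t)
    for name, amp, centre, width in _WAVES:
        if name == "Q":
            amp = profile.q_amp
        if name == "T":
            amp = profile.t_amp
        if name in ("Q", "R", "S"):
            width = width * profile.qrs_width_mult
        y += amp * np.exp(-((t - centre) ** 2) / (2 * width**2))
    if profile.r_prime:
        w = 0.018 * profile.qrs_width_mult
        y += profile.r_prime * np.exp(-((t - 2.2 * w) ** 2) / (2 * w**2))
    if profile.st_offset:
        # smooth plateau between the S wave and the T onset
        rise = 1.0 / (1.0 + np.exp(-(t - 0.07) / 0.012))
        fall = 1.0 / (1.0 + np.exp((t - 0.24) / 0.02))
        y += profile.st_offset * rise * fall
    return profile.amplitude_scale * y


def ecg_source(profile: ECGClassProfile, fs: float, duration: float,
               rng: np.random.Generator):
    """Noiseless single-lead trace plus the beat times used to build it."""
    n = int(round(duration * fs))
    template = beat_template(profile, fs)
    half = len(template) // 2
    source = np.zeros(n)
    beat_times: List[float] = []
    t = profile.rr_mean / 2.0
    while t < duration:
        beat_times.append(t)
        centre = int(round(t * fs))
        lo, hi = centre - half, centre - half + len(template)
        s0, s1 = max(lo, 0), min(hi, n)
        source[s0:s1] += template[s0 - lo:s1 - lo]
        rr = rng.normal(profile.rr_mean, profile.rr_jitter * profile.rr_mean)
        t += max(rr, 0.3 * profile.rr_mean)
    return source, np.asarray(beat_times)


def gen_ecg_record(class_label: str, channels: int = 15, fs: float = 250.0,
                   duration: float = 10.0, seed: int = 0,
                   noise_sigma: float = 0.03,
                   record_id: Optional[str] = None) -> ECGRecord:
    """Generate one multi-channel quasi-ECG record of the given class."""
    if class_label not in CLASS_PROFILES:
        raise ValueError(
            f"unknown class {class_label!r}; expected one of {CLASSES}"
        )
    profile = CLASS_PROFILES[class_label]
    rng = np.random.default_rng(seed)
    source, _ = ecg_source(profile, fs, duration, rng)
    # fixed per-record lead mixture: scale and a small baseline rotation
    gains = rng.uniform(0.4, 1.2, size=channels)
    signs = np.ones(channels)
    if channels >= 4:
        signs[3] = -1.0  # aVR-like inverted lead
    sig = signs[:, None] * gains[:, None] * source[None, :]
    sig = sig + rng.normal(0.0, noise_sigma, size=sig.shape)
    names = list(PTB_CHANNELS[:channels])
    if channels > len(PTB_CHANNELS):
        names += [f"ch{i}" for i in range(len(PTB_CHANNELS), channels)]
    return ECGRecord(sig, fs, names, label=class_label,
                     record_id=record_id or f"{class_label}_{seed}")


#: Class sizes of the five-class PTB diagnostic cohort.
PTB_CLASS_COUNTS = {"HC": 62, "MI": 60, "BBB": 19, "CM": 15, "DR": 14}


def gen_dataset(n_per_class: int | Dict[str, int] = 10, seed: int = 0,
                channels: int = 15, fs: float = 250.0,
                duration: float = 10.0,
                classes: Sequence[str] = CLASSES) -> List[ECGRecord]:
    """Generate a labelled dataset, reproducible per seed.

    ``n_per_class`` may be an int (balanced) or a per-class map; pass
    :data:`PTB_CLASS_COUNTS` for the PTB cohort proportions.
    """
    if isinstance(n_per_class, dict):
        counts = dict(n_per_class)
    else:
        if n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        counts = {c: int(n_per_class) for c in classes}
    ss = np.random.SeedSequence(seed)
    records: List[ECGRecord] = []
    for cls in classes:
        n = counts.get(cls, 0)
        child_seeds = ss.spawn(1)[0].generate_state(n) >> 1  # < 2**31
        for i in range(n):
            records.append(gen_ecg_record(
                cls, channels=channels, fs=fs, duration=duration,
                seed=int(child_seeds[i]), record_id=f"{cls}_{i:03d}"))
    return records
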