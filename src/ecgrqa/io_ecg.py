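"""Reading, writing and resampling of multi-channel ECG records.

Records are exchanged in WFDB format (a plain-text ``.hea`` header plus a
16-bit little-endian ``.dat`` signal file, format 16 with one shared signal
file per record — the layout used by the PTB diagnostic ECG database).
Amplitudes are kept in millivolts throughout the pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy.signal import resample_poly

#: Canonical PTB channel order: 12 conventional leads plus the Frank leads.
PTB_CHANNELS = (
    "i", "ii", "iii", "avr", "avl", "avf",
    "v1", "v2", "v3", "v4", "v5", "v6",
    "vx", "vy", "vz",
)

#: Study classes in fixed order (healthy control first, then disorders).
CLASSES = ("HC", "MI", "BBB", "CM", "DR")

# PTB digitisation: 16 bit over +/-16.384 mV -> 2000 ADC units per mV.
_DEFAULT_GAIN = 2000.0


class FormatError(ValueError):
    """Header and signal files disagree, or a header cannot be parsed."""


@dataclass
class ECGRecord:
    """A multi-channel ECG signal with metadata.

    Attributes
    ----------
    signal : ndarray, shape (channels, samples)
        Physical amplitudes in millivolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered lead names; order is stable across a dataset.
    label : str or None
        Diagnostic class (one of ``CLASSES``) if known.
    record_id : str
    """

    signal: np.ndarray
    fs: float
    channel_names: Sequence[str] = field(default_factory=list)
    label: Optional[str] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


def read_record(path: str | os.PathLike, format: str = "wfdb") -> ECGRecord:
    """Read a WFDB record given the path of its header (with or without ``.hea``).

    Returns physical millivolt samples for all channels at the original
    sampling rate.  Raises ``FileNotFoundError`` for missing files and
    :class:`FormatError` when header and signal file are inconsistent.
    """
    if format != "wfdb":
        raise ValueError(f"unsupported format {format!r}")
    path = str(path)
    hea_path = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(f"header file not found: {hea_path}")
    with open(hea_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = [ln for ln in lines if not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in lines if ln.startswith("#")]
    try:
        rec_tokens = header[0].split()
        record_id = rec_tokens[0]
        n_sig = int(rec_tokens[1])
        fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
        n_samp = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"cannot parse record line of {hea_path}") from exc
    if len(header) - 1 < n_sig:
        raise FormatError(
            f"{hea_path}: record line declares {n_sig} signals but only "
            f"{len(header) - 1} signal lines follow"
        )
    names, gains, baselines, dat_name = [], [], [], None
    for ln in header[1 : 1 + n_sig]:
        tokens = ln.split()
        try:
            fname, fmt = tokens[0], tokens[1]
            gain_tok = tokens[2] if len(tokens) > 2 else "200"
        except IndexError as exc:
            raise FormatError(f"cannot parse signal line {ln!r}") from exc
        if fmt != "16":
            raise FormatError(f"unsupported WFDB signal format {fmt!r}")
        if dat_name is None:
            dat_name = fname
        elif fname != dat_name:
            raise FormatError("multiple signal files per record not supported")
        gain_part = gain_tok.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_part))
            baselines.append(0)
        names.append(tokens[8] if len(tokens) > 8 else f"ch{len(names)}")
    dat_path = os.path.join(os.path.dirname(hea_path), dat_name)
    if not os.path.exists(dat_path):
        raise FileNotFoundError(f"signal file not found: {dat_path}")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samp and raw.size != n_sig * n_samp:
        raise FormatError(
            f"{dat_path}: expected {n_sig}x{n_samp}={n_sig * n_samp} samples, "
            f"file holds {raw.size}"
        )
    if raw.size % n_sig:
        raise FormatError(f"{dat_path}: size {raw.size} not divisible by {n_sig}")
    adc = raw.reshape(-1, n_sig).T.astype(float)
    signal = (adc - np.asarray(baselines)[:, None]) / np.asarray(gains)[:, None]
    label = None
    for c in comments:
        if c.lower().startswith("label:"):
            label = c.split(":", 1)[1].strip() or None
    return ECGRecord(signal, fs, names, label=label, record_id=record_id)


def write_record(record: ECGRecord, path: str | os.PathLike,
                 format: str = "wfdb", gain: float = _DEFAULT_GAIN) -> None:
    """Write *record* as a WFDB format-16 ``.hea``/``.dat`` pair.

    ``path`` is the record path without extension.  Roundtrips through
    :func:`read_record` are lossless up to the 16-bit quantisation step
    (1/gain millivolts).
    """
    if format != "wfdb":
        raise ValueError(f"unsupported format {format!r}")
    if record.n_samples == 0:
        raise ValueError("cannot write a record with no samples")
    path = str(path)
    if path.endswith(".hea"):
        path = path[:-4]
    base = os.path.basename(path)
    adc = np.round(record.signal * gain)
    if np.abs(adc).max(initial=0) > 32767:
        raise ValueError("signal exceeds 16-bit range at this gain")
    adc = adc.astype("<i2")
    adc.T.reshape(-1).tofile(path + ".dat")
    fs_tok = f"{record.fs:g}"
    lines = [f"{base} {record.n_channels} {fs_tok} {record.n_samples}"]
    for name in record.channel_names:
        lines.append(f"{base}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 {name}")
    if record.label is not None:
        lines.append(f"# label: {record.label}")
    with open(path + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")


def downsample(record: ECGRecord, target_fs: float,
               naive: bool = False) -> ECGRecord:
    """Resample *record* to ``target_fs``.

    Default is rational-ratio polyphase resampling (scipy ``resample_poly``),
    whose anti-alias filter is intrinsic to correct decimation; no denoising
    is applied.  ``naive=True`` keeps every k-th sample instead (integer
    ratios only), for strict literal decimation.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs > record.fs:
        raise ValueError(
            f"target_fs {target_fs} exceeds record rate {record.fs}"
        )
    if target_fs == record.fs:
        return replace(record, signal=record.signal.copy())
    if naive:
        ratio = record.fs / target_fs
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("naive decimation requires an integer ratio")
        sig = record.signal[:, :: int(round(ratio))]
    else:
        frac = Fraction(target_fs).limit_denominator(10**6) / Fraction(
            record.fs
        ).limit_denominator(10**6)
        sig = resample_poly(record.signal, frac.numerator, frac.denominator,
                            axis=1)
    return replace(record, signal=sig, fs=float(target_fs))
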