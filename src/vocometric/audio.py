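"""Audio container and WAV I/O.

All DSP in the package flows through :class:`AudioSignal`, a thin immutable
wrapper around a mono float64 sample array plus its sampling rate.  Amplitudes
are dimensionless in [-1, 1]; files are written as 32-bit float WAV so that
round-trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray of float
        Dimensionless amplitudes; finite, peak magnitude at most 1.
    rate : float
        Sampling rate in Hz; strictly positive.
    """

    samples: np.ndarray = field(repr=False)
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"expected mono (1-D) samples, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain non-finite values")
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    def rms(self) -> float:
        """Root-mean-square amplitude."""
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def peak(self) -> float:
        """Peak absolute amplitude."""
        if self.samples.size == 0:
            return 0.0
        return float(np.max(np.abs(self.samples)))


def read_wav(path: str | Path) -> AudioSignal:
    """Read a mono WAV file (integer PCM or float) into an AudioSignal.

    Integer PCM is rescaled to [-1, 1]; stereo input is rejected.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.ndim} channels")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return AudioSignal(samples, float(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an AudioSignal as a 32-bit float mono WAV file."""
    wavfile.write(str(path), int(round(signal.rate)), signal.samples.astype(np.float32))
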