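"""Source-filter vowel synthesis with two controllable formants.

A periodic glottal source (impulse train at the fundamental F0) is passed
through a cascade of two-pole resonators.  The lowest two resonances track
the commanded F1 and F2 trajectory sample-by-sample; an optional fixed
third resonance adds the non-phonetic speaker coloring carried by higher
formants.  Voicing is continuous — there is no volume channel — so a
constant-amplitude source runs for the whole clip and the output is
peak-normalized afterwards.

Each resonator is the standard digital two-pole section
``y[k] = A*x[k] + B*y[k-1] + C*y[k-2]`` with ``r = exp(-pi*bw/fs)``,
``B = 2*r*cos(2*pi*f/fs)``, ``C = -r**2`` and ``A = 1 - B - C`` (unity DC
gain).  Formant commands arrive at the 1-kHz control rate and are linearly
interpolated to the audio rate before the per-sample coefficient update.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .formant_map import FormantTrace

logger = logging.getLogger(__name__)

__all__ = [
    "SynthConfig",
    "Waveform",
    "impulse_train",
    "resonator_coeffs",
    "synthesize",
    "write_wav",
    "read_wav",
    "spectral_peaks",
]


@dataclass(frozen=True)
class SynthConfig:
    """Synthesizer settings (Klatt-conventional defaults).

    fs_audio : audio sample rate, Hz
    f0       : glottal fundamental, Hz
    b1, b2   : bandwidths of the two controlled formants, Hz
    f3_hz/b3 : fixed third resonance (set ``use_f3=False`` to disable)
    amplitude: peak-normalization target in (0, 1]
    """

    fs_audio: int = 16000
    f0: float = 120.0
    b1: float = 80.0
    b2: float = 90.0
    f3_hz: float = 2900.0
    b3: float = 150.0
    use_f3: bool = True
    amplitude: float = 0.9

    def __post_init__(self) -> None:
        if self.fs_audio <= 0:
            raise ValueError("fs_audio must be positive")
        if not (0 < self.f0 < self.fs_audio / 2):
            raise ValueError(f"f0 = {self.f0} must lie in (0, fs/2)")
        if self.b1 <= 0 or self.b2 <= 0 or self.b3 <= 0:
            raise ValueError("bandwidths must be positive")
        if self.use_f3 and not (0 < self.f3_hz < self.fs_audio / 2):
            raise ValueError(f"f3_hz = {self.f3_hz} must lie in (0, fs/2)")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")


@dataclass
class Waveform:
    """Mono audio buffer with samples in [-1, 1]."""

    fs_audio: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains NaN/Inf")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-12:
            raise ValueError("waveform peak exceeds 1")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_audio


def impulse_train(f0: float, fs: float, duration: float) -> np.ndarray:
    """Unit impulse train at ``f0`` via phase accumulation.

    An impulse is emitted whenever the accumulated phase ``f0 * t`` crosses
    an integer, so fractional periods carry across pulses instead of being
    rounded per pulse.  Length is ``round(fs * duration)`` samples.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if not (0 < f0 < fs / 2):
        raise ValueError(f"f0 = {f0} must lie in (0, fs/2)")
    n = int(round(fs * duration))
    cycles = np.floor(f0 * np.arange(1, n + 1) / fs)
    y = np.empty(n)
    y[0] = cycles[0]
    y[1:] = np.diff(cycles)
    return y


def resonator_coeffs(f: float, bw: float, fs: float) -> tuple[float, float, float]:
    """(A, B, C) of the two-pole resonator ``y[k] = A x[k] + B y[k-1] + C y[k-2]``."""
    if not (0 < f < fs / 2):
        raise ValueError(f"resonance frequency {f} Hz must lie in (0, fs/2)")
    if bw <= 0:
        raise ValueError(f"bandwidth must be > 0, got {bw}")
    r = np.exp(-np.pi * bw / fs)
    c = -(r**2)
    b = 2.0 * r * np.cos(2.0 * np.pi * f / fs)
    a = 1.0 - b - c
    return float(a), float(b), float(c)


def _resonate_varying(x: np.ndarray, f_hz: np.ndarray, bw: float, fs: float) -> np.ndarray:
    """Two-pole resonator with per-sample center frequency."""
    r = np.exp(-np.pi * bw / fs)
    c = -(r**2)
    b_arr = 2.0 * r * np.cos(2.0 * np.pi * f_hz / fs)
    a_arr = 1.0 - b_arr - c
    y = np.empty_like(x)
    y1 = 0.0
    y2 = 0.0
    xb = x.tolist()
    bl = b_arr.tolist()
    al = a_arr.tolist()
    out = [0.0] * len(xb)
    for k in range(len(xb)):
        yk = al[k] * xb[k] + bl[k] * y1 + c * y2
        out[k] = yk
        y2 = y1
        y1 = yk
    y[:] = out
    return y


def synthesize(trace: FormantTrace, cfg: SynthConfig | None = None) -> Waveform:
    """Render a formant trace to audio.

    The 1-kHz command trace is linearly interpolated to the audio rate;
    resonator coefficients update every audio sample; the F1 and F2
    sections (plus the fixed F3 section, if enabled) run in cascade on a
    continuous impulse-train source.  Output is peak-normalized to
    ``cfg.amplitude``.
    """
    if cfg is None:
        cfg = SynthConfig()
    if len(trace) == 0:
        return Waveform(cfg.fs_audio, np.empty(0))
    fs = cfg.fs_audio
    duration = len(trace) * trace.dt if len(trace) >= 2 else 1.0 / 1000.0
    n = int(round(fs * duration))
    t_audio = np.arange(n) / fs
    f1 = np.interp(t_audio, trace.time_s, trace.f1_hz)
    f2 = np.interp(t_audio, trace.time_s, trace.f2_hz)
    nyq_margin = 0.95 * fs / 2.0
    n_clip = int(np.sum(f1 > nyq_margin) + np.sum(f2 > nyq_margin))
    if n_clip:
        logger.warning("clipped %d formant commands approaching Nyquist", n_clip)
        f1 = np.minimum(f1, nyq_margin)
        f2 = np.minimum(f2, nyq_margin)
    f1 = np.maximum(f1, 1.0)
    f2 = np.maximum(f2, 1.0)
    src = impulse_train(cfg.f0, fs, duration)
    y = _resonate_varying(src, f1, cfg.b1, fs)
    y = _resonate_varying(y, f2, cfg.b2, fs)
    if cfg.use_f3:
        a3, b3, c3 = resonator_coeffs(cfg.f3_hz, cfg.b3, fs)
        y = sp_signal.lfilter([a3], [1.0, -b3, -c3], y)
    peak = np.max(np.abs(y)) if y.size else 0.0
    if peak > 0:
        y = y * (cfg.amplitude / peak)
    return Waveform(fs, y)


def write_wav(w: Waveform, path) -> None:
    """Write 16-bit PCM mono WAV (round-trip exact within 1/32768)."""
    pcm = np.round(np.clip(w.samples, -1.0, 1.0) * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(w.fs_audio)
        fh.writeframes(pcm.tobytes())


def read_wav(path) -> Waveform:
    """Read a 16-bit PCM mono WAV written by :func:`write_wav`."""
    with wave.open(str(path), "rb") as fh:
        if fh.getsampwidth() != 2 or fh.getnchannels() != 1:
            raise ValueError("expected 16-bit mono PCM")
        fs = fh.getframerate()
        raw = fh.readframes(fh.getnframes())
    samples = np.frombuffer(raw, dtype="<i2").astype(float) / 32767.0
    return Waveform(fs, np.clip(samples, -1.0, 1.0))


def spectral_peaks(
    w: Waveform,
    n_peaks: int = 2,
    smooth_hz: float = 80.0,
    fmax: float | None = None,
    prominence: float = 0.05,
) -> np.ndarray:
    """Lowest ``n_peaks`` local maxima of the smoothed power spectral envelope.

    The Welch power spectrum is smoothed in the log domain with a Gaussian
    kernel wide enough (``smooth_hz``) to erase the harmonic comb of the
    glottal source, leaving the formant envelope; peaks are returned in
    ascending frequency.  Used as the measurement instrument when checking
    that synthesized vowels carry their commanded formants.
    """
    from scipy.ndimage import gaussian_filter1d

    nperseg = min(4096, w.samples.size)
    if w.samples.size < 256:
        raise ValueError("waveform too short for spectral analysis")
    freqs, psd = sp_signal.welch(w.samples, fs=w.fs_audio, nperseg=nperseg)
    df = freqs[1] - freqs[0]
    if fmax is None:
        fmax = 0.45 * w.fs_audio
    keep = freqs <= fmax
    freqs, psd = freqs[keep], psd[keep]
    log_psd = np.log10(psd + 1e-20)
    env = gaussian_filter1d(log_psd, sigma=max(smooth_hz / df, 1.0))
    # prominence (log10-power units) rejects residual harmonic ripple in valleys
    idx, _ = sp_signal.find_peaks(env, prominence=prominence)
    peaks = freqs[idx]
    if peaks.size < n_peaks:
        logger.warning("found only %d of %d requested spectral peaks", peaks.size, n_peaks)
        return peaks
    return peaks[:n_peaks]
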