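"""Call audio analysis: spectrograms, the five acoustic features, feature
normalisation and conflict-stimulus assembly.

The five per-unit parameters are the ones standard in primate bioacoustic
work:

* ``DFB1`` — centre frequency (Hz) of the first (lowest) dominant
  frequency band, i.e. the lowest contiguous run of spectrum bins whose
  mean-spectrum amplitude exceeds a relative threshold below the peak.
* ``DFA2`` — mean over frames of the frequency at which the cumulative
  within-frame energy distribution reaches 50%.
* ``PF`` — overall peak frequency of the mean spectrum (Hz).
* ``FR`` — frequency range: high edge minus low edge of the bins above
  the same relative threshold (Hz).
* ``duration`` — call length in milliseconds.

Spectrograms default to a 512-point FFT, Hamming window and 95% overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy import stats
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "Spectrogram",
    "AcousticConfig",
    "load_wav",
    "spectrogram",
    "extract_features",
    "extract_features_table",
    "normalize_features",
    "build_stimulus",
]


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray  # float, [-1, 1]
    rate: int            # Hz

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if len(self.samples) == 0:
            raise ValueError("waveform is empty")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.rate * 1000.0


@dataclass(frozen=True)
class Spectrogram:
    magnitudes: np.ndarray  # frames x bins, linear amplitude
    frame_times: np.ndarray  # s, frame start times
    bin_freqs: np.ndarray    # Hz
    fft_len: int
    overlap: float
    window: str


@dataclass(frozen=True)
class AcousticConfig:
    """Spectral-analysis settings shared by the feature extractor."""

    fft_len: int = 512
    window: str = "hamming"
    overlap: float = 0.95
    band_threshold_db: float = -20.0  # relative to mean-spectrum peak
    lowcut_hz: float = 1000.0
    lowcut_order: int = 4
    dfa2_quantile: float = 0.5


_PCM_SCALE = {np.dtype("int16"): 32768.0, np.dtype("int32"): 2147483648.0,
              np.dtype("uint8"): 128.0}


def load_wav(path) -> Waveform:
    """Read a RIFF WAV file into a float waveform in [-1, 1].

    Multichannel audio is collapsed to mono by channel averaging; integer
    PCM is rescaled by its full-scale value.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with filename context
        raise ValueError(f"cannot read WAV file {path!r}: {exc}") from exc
    data = np.atleast_1d(data)
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[np.dtype(data.dtype)]
        offset = 128.0 if data.dtype == np.uint8 else 0.0
        data = (data.astype(float) - offset) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return Waveform(samples=data, rate=int(rate))


def spectrogram(w: Waveform, fft_len: int = 512, window: str = "hamming",
                overlap: float = 0.95) -> Spectrogram:
    """Magnitude short-time spectrum with half-open frames.

    Frames cover ``[start, start + fft_len)`` with hop
    ``round(fft_len * (1 - overlap))`` (at least 1); the trailing partial
    frame is dropped.
    """
    x = np.asarray(w.samples, dtype=float)
    if len(x) < fft_len:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than one {fft_len}-sample "
            "frame; zero-pad the input if a spectrum is still wanted"
        )
    hop = max(1, int(round(fft_len * (1.0 - overlap))))
    frames = sliding_window_view(x, fft_len)[::hop]
    win = sps.get_window(window, fft_len, fftbins=True)
    mags = np.abs(np.fft.rfft(frames * win, axis=1))
    bin_freqs = np.fft.rfftfreq(fft_len, d=1.0 / w.rate)
    frame_times = np.arange(frames.shape[0]) * hop / w.rate
    return Spectrogram(magnitudes=mags, frame_times=frame_times,
                       bin_freqs=bin_freqs, fft_len=fft_len,
                       overlap=overlap, window=window)


def _band_edges(mean_spec: np.ndarray, threshold_db: float) -> np.ndarray:
    thr = mean_spec.max() * 10.0 ** (threshold_db / 20.0)
    return mean_spec >= thr


def extract_features(w: Waveform, cfg: AcousticConfig | None = None) -> dict[str, float]:
    """Extract the five acoustic parameters from one call unit.

    All frequency parameters derive from the magnitude spectrogram;
    duration is the sample count over the rate.  Raises on an all-zero
    signal, where the spectral features are undefined.
    """
    cfg = cfg or AcousticConfig()
    x = np.asarray(w.samples, dtype=float)
    if not np.any(x):
        raise ValueError("degenerate all-zero signal: acoustic features undefined")
    spec = spectrogram(w, cfg.fft_len, cfg.window, cfg.overlap)
    mags = spec.magnitudes
    freqs = spec.bin_freqs
    mean_spec = mags.mean(axis=0)

    pf = float(freqs[int(np.argmax(mean_spec))])

    above = _band_edges(mean_spec, cfg.band_threshold_db)
    idx = np.nonzero(above)[0]
    fr = float(freqs[idx[-1]] - freqs[idx[0]])

    # first dominant band: lowest contiguous run of above-threshold bins
    first = idx[0]
    last = first
    while last + 1 < len(above) and above[last + 1]:
        last += 1
    dfb1 = float(0.5 * (freqs[first] + freqs[last]))

    energy = mags ** 2
    tot = energy.sum(axis=1)
    ok = tot > 0
    cum = np.cumsum(energy[ok], axis=1) / tot[ok, None]
    med_idx = np.argmax(cum >= cfg.dfa2_quantile, axis=1)
    dfa2 = float(freqs[med_idx].mean())

    return {
        "DFB1": dfb1,
        "DFA2": dfa2,
        "PF": pf,
        "FR": fr,
        "duration": w.duration_ms,
    }


def extract_features_table(meta: pd.DataFrame,
                           cfg: AcousticConfig | None = None) -> pd.DataFrame:
    """Run :func:`extract_features` over a metadata table with a ``file``
    column, keeping the ``unit_id, bout_id, caller_id`` keys."""
    rows = []
    for _, r in meta.iterrows():
        feats = extract_features(load_wav(r["file"]), cfg)
        rows.append({"unit_id": r["unit_id"], "bout_id": r["bout_id"],
                     "caller_id": r["caller_id"]} | feats)
    return pd.DataFrame(rows)


def normalize_features(table: pd.DataFrame, log_rule: str | dict[str, bool] = "auto",
                       feature_cols: list[str] | None = None,
                       ddof: int = 0) -> tuple[pd.DataFrame, dict[str, str]]:
    """Log-transform features where indicated, then z-score each column.

    ``log_rule`` may be ``"auto"`` (log a column when a Shapiro-Wilk test
    rejects normality at 0.05 and the logged column is less skewed),
    ``"none"``, or an explicit ``{feature: bool}`` mapping.  Returns the
    transformed table and the per-feature transform flags
    (``"raw"`` or ``"log"``).
    """
    from .synthetic import FEATURE_NAMES

    cols = feature_cols or [c for c in FEATURE_NAMES if c in table.columns]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to normalise")
    out = table.copy()
    flags: dict[str, str] = {}
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        if isinstance(log_rule, dict):
            use_log = bool(log_rule.get(c, False))
        elif log_rule == "auto":
            use_log = _auto_log(x)
        elif log_rule == "none":
            use_log = False
        else:
            raise ValueError(f"unknown log_rule {log_rule!r}")
        if use_log:
            if np.any(x <= 0):
                raise ValueError(f"feature {c!r} has non-positive values; cannot log")
            x = np.log(x)
        sd = x.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"feature {c!r} has zero variance")
        out[c] = (x - x.mean()) / sd
        flags[c] = "log" if use_log else "raw"
    return out, flags


def _auto_log(x: np.ndarray) -> bool:
    if np.any(x <= 0) or np.ptp(x) == 0:
        return False
    p = stats.shapiro(x).pvalue if 3 <= len(x) <= 5000 else 1.0
    if p >= 0.05:
        return False
    return abs(stats.skew(np.log(x))) < abs(stats.skew(x))


def build_stimulus(a: Waveform, b: Waveform, duration_s: float = 4.0,
                   lowcut_hz: float = 1000.0, lowcut_order: int = 4) -> Waveform:
    """Overlay two conflict calls into one playback stimulus.

    Both calls start synchronously; the mix is cut or zero-padded to
    exactly ``duration_s`` seconds, high-pass filtered (zero-phase
    Butterworth, cutoff ``lowcut_hz``) to strip low-frequency noise, and
    peak-normalised below full scale.
    """
    if a.rate != b.rate:
        raise ValueError(f"sample-rate mismatch: {a.rate} vs {b.rate}")
    n_out = int(round(duration_s * a.rate))

    def _fit(x: np.ndarray) -> np.ndarray:
        if len(x) > n_out:
            import warnings

            warnings.warn("input longer than the stimulus window; truncating",
                          stacklevel=3)
            return x[:n_out]
        return np.pad(x, (0, n_out - len(x)))

    mix = _fit(np.asarray(a.samples, float)) + _fit(np.asarray(b.samples, float))
    sos = sps.butter(lowcut_order, lowcut_hz, btype="highpass", fs=a.rate,
                     output="sos")
    mix = sps.sosfiltfilt(sos, mix)
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = 0.95 * mix / peak
    return Waveform(samples=mix, rate=a.rate)
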