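"""Wiener entropy (spectral flatness) as an objective complexity score.

Spectral flatness is the ratio of the geometric to the arithmetic mean
of a power spectrum: 1 for a perfectly uniform (white) spectrum,
approaching 0 as power concentrates in a single component (a pure
tone).  An excerpt's score is obtained by cutting the waveform into
non-overlapping segments (50 ms by default, 20 ms as the robustness
alternative), computing each segment's power spectrum, taking its
flatness, and aggregating across segments.

Within a segment the power spectrum is estimated by averaging the
periodograms of consecutive rectangular sub-frames (Bartlett/Welch
averaging, 128 samples per sub-frame by default).  Averaging matters: a
single raw periodogram of white noise has flatness exp(-gamma) ~ 0.56,
because its bins are exponentially distributed however long the
segment; averaging K independent periodograms drives the flatness of a
flat-spectrum signal to exp(psi(K) - log K) -> 1, giving the measure
its intended anchors (white noise near 1, pure tone near 0).  Pass
``subframe=None`` for the raw single-periodogram variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile
from scipy.stats import kendalltau

__all__ = [
    "EntropyProfile",
    "spectral_flatness",
    "wiener_entropy",
    "entropy_window_agreement",
    "read_wav",
    "score_directory",
]


class DegenerateAudioError(ValueError):
    """The input carries no spectral information (e.g. all-zero)."""


def spectral_flatness(power_spectrum: np.ndarray) -> float:
    """Geometric over arithmetic mean of a non-negative power spectrum.

    Equals 1 iff the spectrum is constant; tends to 0 as the power
    concentrates in one bin.  Bins that are exactly zero drive the
    geometric mean — and hence the flatness — to zero.
    """
    p = np.asarray(power_spectrum, float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("power spectrum must be a non-empty 1-d vector")
    if (p < 0).any() or not np.all(np.isfinite(p)):
        raise ValueError("power spectrum must be finite and non-negative")
    am = p.mean()
    if am == 0:
        raise DegenerateAudioError("all-zero power spectrum")
    if (p == 0).any():
        return 0.0
    gm = np.exp(np.mean(np.log(p)))
    return float(min(gm / am, 1.0))


@dataclass(frozen=True)
class EntropyProfile:
    """Per-segment spectral flatness of one excerpt and its aggregate."""

    window_ms: float
    sample_rate: int
    per_segment_flatness: np.ndarray
    aggregate: float
    n_segments: int


def _segment_spectrum(
    seg: np.ndarray, subframe: int | None, window: str
) -> np.ndarray:
    if subframe is None:
        spec = np.abs(np.fft.rfft(seg)) ** 2
        return spec[1:]  # drop DC
    nper = min(subframe, seg.size)
    _, p = signal.welch(
        seg, window=window, nperseg=nper, noverlap=0, detrend=False, scaling="spectrum"
    )
    return p[1:]


def wiener_entropy(
    waveform: np.ndarray,
    sample_rate: int,
    window_ms: float = 50.0,
    *,
    aggregate: str = "mean",
    subframe: int | None = 128,
    window: str = "boxcar",
) -> EntropyProfile:
    """Windowed spectral flatness of a waveform.

    The waveform (mono, or stereo to be down-mixed) is split into
    ``floor(duration / window_ms)`` non-overlapping segments; each
    segment's power spectrum (DC bin excluded) yields one flatness value
    and ``aggregate`` ("mean", "median" or "log_mean") combines them.
    Silent segments carry no spectral information and are excluded with
    a warning.  The score is invariant to amplitude scaling.
    """
    y = np.asarray(waveform, float)
    if y.ndim == 2:  # stereo: average channels
        y = y.mean(axis=1 if y.shape[1] in (1, 2) else 0)
    if y.ndim != 1:
        raise ValueError("waveform must be 1-d (mono) or 2-d (stereo)")
    if not np.all(np.isfinite(y)):
        raise ValueError("waveform contains non-finite samples")
    seg_len = int(round(window_ms / 1000 * sample_rate))
    if seg_len < 2 or y.size < seg_len:
        raise ValueError(
            f"waveform shorter than one {window_ms} ms window at {sample_rate} Hz"
        )
    n_seg = y.size // seg_len
    vals = np.full(n_seg, np.nan)
    n_silent = 0
    for i in range(n_seg):
        seg = y[i * seg_len : (i + 1) * seg_len]
        spec = _segment_spectrum(seg, subframe, window)
        if spec.sum() == 0:
            n_silent += 1
            continue
        vals[i] = spectral_flatness(spec)
    if n_silent:
        warnings.warn(
            f"{n_silent} of {n_seg} segments are silent; flatness undefined there",
            stacklevel=2,
        )
    good = vals[~np.isnan(vals)]
    if good.size == 0:
        raise DegenerateAudioError("every segment is silent")
    if aggregate == "mean":
        agg = float(good.mean())
    elif aggregate == "median":
        agg = float(np.median(good))
    elif aggregate == "log_mean":
        agg = float(np.exp(np.mean(np.log(np.maximum(good, 1e-300)))))
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return EntropyProfile(
        window_ms=float(window_ms),
        sample_rate=int(sample_rate),
        per_segment_flatness=vals,
        aggregate=agg,
        n_segments=int(n_seg),
    )


def entropy_window_agreement(
    aggregates_50: np.ndarray, aggregates_20: np.ndarray
) -> float:
    """Kendall rank agreement between 50 ms and 20 ms entropy scores."""
    a, b = np.asarray(aggregates_50, float), np.asarray(aggregates_20, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need the same >= 3 excerpts under both window lengths")
    return float(kendalltau(a, b).statistic)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM/float WAV as a mono float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    y = np.asarray(data)
    if y.dtype.kind == "i":
        y = y.astype(float) / float(np.iinfo(data.dtype).max)
    elif y.dtype.kind == "u":  # 8-bit unsigned PCM
        y = (y.astype(float) - 128.0) / 128.0
    else:
        y = y.astype(float)
    if y.ndim == 2:
        y = y.mean(axis=1)
    return y, int(rate)


def score_directory(
    directory: str | Path, window_ms: float = 50.0, **kwargs
) -> "pd.DataFrame":
    """Wiener-entropy scores for every .wav file in a directory.

    Returns a DataFrame (excerpt_id, window_ms, aggregate, n_segments)
    keyed by file stem, mergeable into a stimulus table.
    """
    import pandas as pd

    rows = []
    for path in sorted(Path(directory).glob("*.wav")):
        y, sr = read_wav(path)
        prof = wiener_entropy(y, sr, window_ms, **kwargs)
        rows.append(
            {
                "excerpt_id": path.stem,
                "window_ms": prof.window_ms,
                "aggregate": prof.aggregate,
                "n_segments": prof.n_segments,
            }
        )
    return pd.DataFrame(rows)
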