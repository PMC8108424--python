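"""Resting-state Morlet wavelet spectra and beta-band power.

The transform is an analytic (one-sided) Morlet filter bank on
log-spaced center frequencies, 12 voices per octave, with a center
frequency to bandwidth product of 6.  Row powers are normalized by the
filter-bank overlap constant so that summing rows over a frequency
band estimates the signal variance within that band; ``cwt_band_power``
therefore returns a band-integrated power (mV^2), and band powers over
a partition of the analysis range add up to the broadband variance (to
within the wavelet leakage tolerance, about 20%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .core_io import ChannelRole, TimeSeriesRecording

FMIN_HZ = 1.0
FMAX_HZ = 200.0
VOICES_PER_OCTAVE = 12
W0 = 6.0  # center frequency / bandwidth product
BETA_BAND = (14.0, 30.0)


class SpectralError(ValueError):
    pass


@dataclass
class BandPowerResult:
    channel: str
    band: tuple[float, float]
    power: float  # mV^2, band-integrated wavelet power
    z: float = float("nan")  # within-subject z-score across channels


def morlet_frequencies(
    fmin: float = FMIN_HZ, fmax: float = FMAX_HZ, voices: int = VOICES_PER_OCTAVE
) -> np.ndarray:
    n_octaves = np.log2(fmax / fmin)
    n = int(np.floor(n_octaves * voices)) + 1
    return fmin * 2.0 ** (np.arange(n) / voices)


def _overlap_constant(voices: int = VOICES_PER_OCTAVE, w0: float = W0) -> float:
    # sum_m exp(-(w0 * m * ln r)^2) for the log-spaced grid ratio r = 2^(1/voices)
    m = np.arange(-50, 51)
    return float(np.sum(np.exp(-((w0 * m * np.log(2.0) / voices) ** 2))))


def cwt_power_rows(
    x: np.ndarray, sample_rate: float, freqs: np.ndarray | None = None, w0: float = W0
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged analytic-Morlet power per frequency row.

    Returns ``(freqs, row_power)`` where row powers are normalized such
    that their sum over rows approximates the signal variance.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = morlet_frequencies()
    n = len(x)
    X = np.fft.fft(x - x.mean())
    f = np.fft.fftfreq(n, d=1.0 / sample_rate)
    K = _overlap_constant(w0=w0)
    rows = np.empty(len(freqs))
    for j, fj in enumerate(freqs):
        sigma_f = fj / w0
        H = np.where(f > 0, np.exp(-((f - fj) ** 2) / (2.0 * sigma_f**2)), 0.0)
        wj = np.fft.ifft(X * H)
        rows[j] = 2.0 * np.mean(np.abs(wj) ** 2) / K
    return freqs, rows


def cwt_band_power(
    x: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = BETA_BAND,
    max_analysis_rate: float = 1000.0,
) -> float:
    """Band-integrated Morlet power (mV^2) of one signal.

    Signals sampled far above the analysis range are decimated first
    (anti-aliased polyphase resampling) to keep the transform cheap.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = band
    if not 0 < lo < hi:
        raise SpectralError(f"bad band {band}")
    if len(x) < 2 * sample_rate / lo:
        raise SpectralError(
            f"signal too short: need >= 2 periods of {lo} Hz "
            f"({2 * sample_rate / lo:.0f} samples), got {len(x)}"
        )
    fs = sample_rate
    q = int(fs // max_analysis_rate)
    if q > 1:
        x = sps.resample_poly(x, 1, q)
        fs = fs / q
    freqs, rows = cwt_power_rows(x, fs)
    m = (freqs >= lo) & (freqs <= hi)
    if not m.any():
        raise SpectralError(f"no analysis frequencies inside band {band}")
    return float(rows[m].sum())


def band_power_by_channel(
    rec: TimeSeriesRecording,
    band: tuple[float, float] = BETA_BAND,
    rest_interval: tuple[float, float] | None = None,
) -> list[BandPowerResult]:
    """Beta power per recording channel, with within-subject z-scores."""
    chans = rec.channels_with_role(ChannelRole.RING_RECORD, ChannelRole.SEGMENT_RECORD)
    if not chans:
        raise SpectralError("recording has no recording-role channels")
    fs = rec.sample_rate
    if rest_interval is None:
        sl = slice(None)
    else:
        sl = slice(int(rest_interval[0] * fs), int(rest_interval[1] * fs))
    powers = [
        cwt_band_power(rec.signals[rec.channel_index(ch.label), sl], fs, band) for ch in chans
    ]
    zs = zscore(np.array(powers))
    return [
        BandPowerResult(channel=ch.label, band=band, power=p, z=z)
        for ch, p, z in zip(chans, powers, zs)
    ]


def zscore(x: np.ndarray) -> np.ndarray:
    """Sample z-score (ddof=1); constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def beta_feature_association(
    beta: list[BandPowerResult], features: pd.DataFrame
) -> dict[str, float]:
    """Pearson correlation of z-scored beta power with z-scored evoked areas.

    ``features`` needs columns ``channel``, ``erna_area`` and/or
    ``r1_area``; correlations are computed across channels within the
    subject.  Requires >= 3 channels with both measures.
    """
    beta_df = pd.DataFrame({"channel": [b.channel for b in beta], "beta": [b.power for b in beta]})
    merged = beta_df.merge(features, on="channel", how="inner")
    if len(merged) < 3:
        raise SpectralError(f"need >=3 paired channels, got {len(merged)}")
    out: dict[str, float] = {"n_channels": len(merged)}
    bz = zscore(merged["beta"].to_numpy())
    for col, key in [("erna_area", "r_beta_erna"), ("r1_area", "r_beta_r1")]:
        if col in merged.columns:
            r, _ = stats.pearsonr(bz, zscore(merged[col].to_numpy()))
            out[key] = float(r)
    return out


__all__ = [
    "BETA_BAND",
    "BandPowerResult",
    "SpectralError",
    "band_power_by_channel",
    "beta_feature_association",
    "cwt_band_power",
    "cwt_power_rows",
    "morlet_frequencies",
    "zscore",
]
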