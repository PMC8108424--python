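"""R1/ERNA feature extraction, paired-pulse-ratio curves, and
refractory-period estimation.

Response magnitude defaults to the rectified area of the component
window; peak-to-trough amplitude is available as an alternative.  The
absolute refractory period is the first ISI, scanning *descending*,
heading a run of 3 consecutive paired-pulse ratios < 0.2; the relative
refractory period is the first ISI, scanning *ascending*, heading a run
of 3 consecutive ratios > 0.98.  Both endpoints of each qualifying run
are reported alongside the point estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_io import FeatureTable
from .preprocess import CompositeEP, TemplateResponse

R1_BLANK_MS = 0.1
R1_PEAK_WINDOW = (0.1, 0.55)
R1_TROUGH_WINDOW = (0.4, 1.5)
R1_AREA_END_MS = 1.5
ERNA_WINDOW = (3.0, 7.0)
FACILITATION_MARGIN = 0.05


class FeatureError(ValueError):
    pass


@dataclass
class R1Features:
    present: bool
    peak_lat: float = math.nan  # ms
    peak_amp: float = math.nan  # mV
    trough_lat: float = math.nan  # ms
    trough_amp: float = math.nan  # mV, positive magnitude
    area: float = math.nan  # mV*ms, rectified over [blank, 1.5] ms


@dataclass
class ErnaFeatures:
    present: bool
    peak_lat: float = math.nan  # ms, in [3, 7]
    peak_amp: float = math.nan  # mV
    area: float = math.nan  # mV*ms, rectified over [3, 7] ms


@dataclass
class RefractoryProfile:
    """PPR-vs-ISI curves plus refractory/facilitation summaries."""

    isis: np.ndarray  # ms, ascending
    ppr: dict[str, np.ndarray] = field(default_factory=dict)  # component -> ratios
    arp: float | None = None
    rrp: float | None = None
    arp_run: tuple[float, float] | None = None  # (smallest, largest) ISI of the run
    rrp_run: tuple[float, float] | None = None
    facilitation_isis: dict[str, np.ndarray] = field(default_factory=dict)


def _window_slice(times_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    if w1 <= w0:
        raise FeatureError(f"empty window {window}")
    if w0 < times_ms[0] - 1e-9 or w1 > times_ms[-1] + 1e-9:
        raise FeatureError(
            f"window {window} outside waveform support "
            f"[{times_ms[0]:g}, {times_ms[-1]:g}] ms"
        )
    return (times_ms >= w0 - 1e-9) & (times_ms <= w1 + 1e-9)


def response_area(
    waveform: np.ndarray, times_ms: np.ndarray, window: tuple[float, float]
) -> float:
    """Rectified (absolute-value) trapezoidal integral over the window, mV*ms."""
    m = _window_slice(times_ms, window)
    if m.sum() < 2:
        raise FeatureError(f"window {window} contains fewer than two samples")
    return float(np.trapezoid(np.abs(waveform[m]), times_ms[m]))


def _largest_local_extremum(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    window: tuple[float, float],
    threshold: float,
    minimum: bool = False,
) -> tuple[float, float] | None:
    """(latency, magnitude) of the largest qualifying local extremum, or None."""
    m = _window_slice(times_ms, window)
    seg = -waveform[m] if minimum else waveform[m]
    t = times_ms[m]
    idx, _ = find_peaks(seg)
    idx = idx[seg[idx] > threshold]
    if idx.size == 0:
        return None
    best = idx[np.argmax(seg[idx])]
    return float(t[best]), float(seg[best])


def detect_r1(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    noise_sd: float,
    blank: float = R1_BLANK_MS,
    peak_window: tuple[float, float] = R1_PEAK_WINDOW,
    trough_window: tuple[float, float] = R1_TROUGH_WINDOW,
    k_presence: float = 3.0,
) -> R1Features:
    """Locate the early biphasic response.

    The peak is the largest local maximum in ``peak_window`` exceeding
    ``k_presence * noise_sd``; the trough is the largest local minimum in
    ``trough_window`` later than the peak.  Absence is a value, not an
    error.  ``area`` is the rectified integral over [blank, 1.5] ms and
    is reported whenever the peak is present.
    """
    if noise_sd < 0:
        raise FeatureError("noise_sd must be >= 0")
    thr = k_presence * noise_sd
    peak = _largest_local_extremum(waveform, times_ms, peak_window, thr)
    if peak is None:
        return R1Features(present=False)
    peak_lat, peak_amp = peak
    out = R1Features(present=True, peak_lat=peak_lat, peak_amp=peak_amp)
    trough = _largest_local_extremum(
        waveform, times_ms, (max(trough_window[0], peak_lat), trough_window[1]), thr, minimum=True
    )
    if trough is not None and trough[0] > peak_lat:
        out.trough_lat, out.trough_amp = trough
    out.area = response_area(waveform, times_ms, (blank, R1_AREA_END_MS))
    return out


def detect_erna(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    noise_sd: float,
    window: tuple[float, float] = ERNA_WINDOW,
    k_presence: float = 3.0,
) -> ErnaFeatures:
    """Largest local maximum in the 3-7 ms window; present above k*noise."""
    if noise_sd < 0:
        raise FeatureError("noise_sd must be >= 0")
    area = response_area(waveform, times_ms, window)
    peak = _largest_local_extremum(waveform, times_ms, window, k_presence * noise_sd)
    if peak is None:
        return ErnaFeatures(present=False, area=area)
    return ErnaFeatures(present=True, peak_lat=peak[0], peak_amp=peak[1], area=area)


def estimate_noise_sd(
    waveform: np.ndarray, times_ms: np.ndarray, window: tuple[float, float] = (-5.0, -0.5)
) -> float:
    """Baseline noise SD from the pre-stimulus interval."""
    m = _window_slice(times_ms, window)
    return float(np.std(waveform[m]))


COMPONENT_WINDOWS = {"r1": (R1_BLANK_MS, R1_AREA_END_MS), "erna": ERNA_WINDOW}


def ppr_curve(
    test_composites: list[CompositeEP],
    template: TemplateResponse,
    component: str,
    window: tuple[float, float] | None = None,
    magnitude: str = "area",
) -> RefractoryProfile:
    """Paired-pulse ratio versus ISI for one response component.

    ppr(isi) = magnitude(test composite at isi) / magnitude(template),
    with magnitude either the rectified area over the component window
    (default) or the peak-to-trough amplitude within it.
    """
    if component not in COMPONENT_WINDOWS and window is None:
        raise FeatureError(f"unknown component {component!r}; pass window= explicitly")
    if magnitude not in ("area", "peak_to_trough"):
        raise FeatureError(f"magnitude must be 'area' or 'peak_to_trough', got {magnitude!r}")
    win = window if window is not None else COMPONENT_WINDOWS[component]

    def mag(wave: np.ndarray, times: np.ndarray) -> float:
        if magnitude == "area":
            return response_area(wave, times, win)
        m = _window_slice(times, win)
        return float(wave[m].max() - wave[m].min())

    denom = mag(template.waveform, template.times_ms)
    if denom <= 0.0:
        raise FeatureError(f"template {component} magnitude is zero; cannot normalize")
    pairs = sorted(test_composites, key=lambda c: c.isi)
    isis = np.array([c.isi for c in pairs])
    ratios = np.array([mag(c.waveform, c.times_ms) / denom for c in pairs])
    prof = RefractoryProfile(isis=isis, ppr={component: ratios})
    prof.facilitation_isis[component] = isis[ratios > 1.0 + FACILITATION_MARGIN]
    return prof


def _run_scan(
    isis: np.ndarray, flags: np.ndarray, run: int, descending: bool
) -> tuple[float, tuple[float, float]] | None:
    """First run of ``run`` consecutive flagged ISIs in scan order.

    Returns (first-encountered ISI of the run, (min, max) ISI of the run).
    """
    order = range(len(isis) - 1, -1, -1) if descending else range(len(isis))
    streak: list[int] = []
    for i in order:
        if flags[i]:
            streak.append(i)
            if len(streak) == run:
                lead = streak[0]
                lo, hi = min(streak), max(streak)
                return float(isis[lead]), (float(isis[lo]), float(isis[hi]))
        else:
            streak = []
    return None


def estimate_arp(
    profile: RefractoryProfile,
    threshold: float = 0.2,
    run: int = 3,
    component: str = "r1",
) -> float | None:
    """Absolute refractory period from the PPR curve (descending scan).

    Returns the largest ISI of the first run of ``run`` consecutive
    ratios below ``threshold``, or None when no such run exists.  Run
    endpoints are stored on the profile.
    """
    ppr = _component_curve(profile, component)
    if len(profile.isis) < run:
        raise FeatureError(f"need at least {run} ISIs")
    hit = _run_scan(profile.isis, ppr < threshold, run, descending=True)
    if hit is None:
        profile.arp, profile.arp_run = None, None
        return None
    profile.arp, profile.arp_run = hit
    return hit[0]


def estimate_rrp(
    profile: RefractoryProfile,
    threshold: float = 0.98,
    run: int = 3,
    component: str = "r1",
) -> float | None:
    """Relative refractory period (ascending scan): smallest ISI of the
    first run of ``run`` consecutive ratios above ``threshold``."""
    ppr = _component_curve(profile, component)
    if len(profile.isis) < run:
        raise FeatureError(f"need at least {run} ISIs")
    hit = _run_scan(profile.isis, ppr > threshold, run, descending=False)
    if hit is None:
        profile.rrp, profile.rrp_run = None, None
        return None
    profile.rrp, profile.rrp_run = hit
    return hit[0]


def _component_curve(profile: RefractoryProfile, component: str) -> np.ndarray:
    if component not in profile.ppr:
        if len(profile.ppr) == 1:
            component = next(iter(profile.ppr))
        else:
            raise FeatureError(f"profile has no {component!r} curve")
    curve = np.asarray(profile.ppr[component])
    if len(curve) != len(profile.isis):
        raise FeatureError("ppr curve length does not match ISI grid")
    return curve


def latency_shifts(
    test_features: dict[float, dict[str, R1Features | ErnaFeatures]],
    template_features: dict[str, R1Features | ErnaFeatures],
) -> FeatureTable:
    """Latency change (test minus template, ms; positive = delayed) per ISI.

    ``test_features`` maps isi -> {"r1": R1Features, "erna": ErnaFeatures};
    components absent from the template or undetected at an ISI yield NaN.
    """
    rows = []
    for isi in sorted(test_features):
        feats = test_features[isi]
        row: dict[str, float] = {"isi_ms": isi}
        r1t = template_features.get("r1")
        r1 = feats.get("r1")
        if isinstance(r1t, R1Features) and r1t.present and isinstance(r1, R1Features) and r1.present:
            row["r1_peak_dlat_ms"] = r1.peak_lat - r1t.peak_lat
            row["r1_trough_dlat_ms"] = r1.trough_lat - r1t.trough_lat
        else:
            row["r1_peak_dlat_ms"] = math.nan
            row["r1_trough_dlat_ms"] = math.nan
        et = template_features.get("erna")
        e = feats.get("erna")
        if isinstance(et, ErnaFeatures) and et.present and isinstance(e, ErnaFeatures) and e.present:
            row["erna_dlat_ms"] = e.peak_lat - et.peak_lat
        else:
            row["erna_dlat_ms"] = math.nan
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["isi_ms", "r1_peak_dlat_ms", "r1_trough_dlat_ms", "erna_dlat_ms"])
    return FeatureTable(
        frame=frame,
        key=("isi_ms",),
        units={"isi_ms": "ms", "r1_peak_dlat_ms": "ms", "r1_trough_dlat_ms": "ms", "erna_dlat_ms": "ms"},
    )


def extract_all_features(
    composite: CompositeEP | TemplateResponse, noise_sd: float, **detect_kwargs
) -> dict[str, R1Features | ErnaFeatures]:
    """Convenience: R1 + ERNA features of one waveform."""
    wave, times = composite.waveform, composite.times_ms
    return {
        "r1": detect_r1(wave, times, noise_sd, **detect_kwargs.get("r1", {})),
        "erna": detect_erna(wave, times, noise_sd, **detect_kwargs.get("erna", {})),
    }


__all__ = [
    "COMPONENT_WINDOWS",
    "ErnaFeatures",
    "FeatureError",
    "R1Features",
    "RefractoryProfile",
    "detect_erna",
    "detect_r1",
    "estimate_arp",
    "estimate_noise_sd",
    "estimate_rrp",
    "extract_all_features",
    "latency_shifts",
    "ppr_curve",
    "response_area",
]
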