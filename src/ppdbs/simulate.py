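"""Synthetic paired-pulse stimulation sessions with known ground truth.

The generator reproduces the phenomenology the downstream stages are
built to measure: a polarity-locked stimulus artifact, a biphasic
short-latency evoked response (R1) with absolute/relative refractory
dynamics and latency delays, a later damped oscillation (ERNA) with
ISI-dependent facilitation and latency hastening, and per-channel beta
plus 1/f background.  Every generative constant lives in
:class:`SimConfig`, and :func:`synthesize_session` echoes them in a
ground-truth record so parameter recovery can be tested end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import fsolve

from .core_io import (
    ChannelInfo,
    ChannelRole,
    StimEvent,
    TimeSeriesRecording,
    write_recording,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one synthetic session.

    Amplitudes in mV, times/latencies in ms, frequencies in Hz.
    """

    seed: int = 0
    sample_rate: float = 100_000.0
    # paired-pulse schedule
    n_isi: int = 90
    isi_short_range: tuple[float, float] = (0.18, 16.0)
    isi_template_range: tuple[float, float] = (20.0, 30.0)
    n_template_isi: int = 4
    reps_per_polarity: int = 1
    pause_range: tuple[float, float] = (35.0, 45.0)
    # stimulus artifact (exponential, truncated at 0.1 ms, sign = polarity)
    artifact_amp: float = 20.0
    artifact_decay: float = 0.03
    # R1: difference-of-Gaussians biphasic response
    r1_peak_amp: float = 1.0
    r1_peak_lat: float = 0.30
    r1_trough_amp: float = 0.5
    r1_trough_lat: float = 0.70
    # refractory dynamics
    arp: float = 0.56
    rrp: float = 2.94
    latency_delay_max: float = 0.3
    latency_delay_tau: float = 1.0
    # ERNA: damped sinusoid
    erna_present: bool = True
    erna_amp: float = 0.3
    erna_freq: float = 300.0
    erna_onset: float = 3.5
    erna_decay: float = 2.0
    facil_bands: tuple[tuple[float, float, float], ...] = ((2.5, 0.8, 0.4), (7.0, 1.5, 0.3))
    hasten_per_gain: float = 0.3
    # background
    noise_sd: float = 0.01
    beta_freq: float = 20.0
    beta_amp_per_channel: tuple[float, ...] = (0.005, 0.002)
    beta_erna_coupling: float = 0.0
    pink_noise_amp: float = 0.0
    rest_duration: float = 10.0  # stimulation-free prologue, seconds
    # per-recording-channel coupling of evoked response and artifact
    channel_response_gain: tuple[float, ...] = (1.0, 0.25)
    channel_artifact_gain: tuple[float, ...] = (1.0, 0.5)

    @property
    def n_short_isi(self) -> int:
        return self.n_isi - self.n_template_isi

    @property
    def n_record_channels(self) -> int:
        return len(self.beta_amp_per_channel)

    def validate(self) -> None:
        if not 0 < self.arp < self.rrp:
            raise SimulationError(f"need 0 < arp < rrp, got {self.arp}, {self.rrp}")
        lo, hi = self.isi_short_range
        tlo, thi = self.isi_template_range
        if not (0 < lo < hi <= tlo < thi):
            raise SimulationError(
                f"isi ranges must be ordered and disjoint: {self.isi_short_range}, "
                f"{self.isi_template_range}"
            )
        if self.n_short_isi < 1 or self.n_template_isi < 1:
            raise SimulationError("n_isi must exceed n_template_isi >= 1")
        for name in ("artifact_amp", "r1_peak_amp", "r1_trough_amp", "erna_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if len(self.channel_response_gain) != self.n_record_channels:
            raise SimulationError("channel_response_gain length must match beta_amp_per_channel")
        if len(self.channel_artifact_gain) != self.n_record_channels:
            raise SimulationError("channel_artifact_gain length must match beta_amp_per_channel")
        if self.pause_range[0] > self.pause_range[1]:
            raise SimulationError("pause_range must be ordered")


@dataclass(frozen=True)
class PairedPulseSchedule:
    """Randomized presentation order of (ISI, polarity) conditions."""

    isis: tuple[float, ...]  # unique, ascending
    order: tuple[tuple[float, int], ...]  # (isi_ms, polarity) per pair
    pauses: tuple[float, ...]  # ms, one per pair


def build_schedule(cfg: SimConfig) -> PairedPulseSchedule:
    """Log-spaced short ISIs plus the long (template) ISIs, shuffled by seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    short = np.geomspace(*cfg.isi_short_range, cfg.n_short_isi)
    template = np.linspace(*cfg.isi_template_range, cfg.n_template_isi)
    isis = np.concatenate([short, template])
    if len(np.unique(isis)) != cfg.n_isi:
        raise SimulationError("ISI grid has duplicates")
    conditions = [
        (float(isi), pol)
        for isi in isis
        for pol in (+1, -1)
        for _ in range(cfg.reps_per_polarity)
    ]
    perm = rng.permutation(len(conditions))
    order = tuple(conditions[i] for i in perm)
    pauses = tuple(float(p) for p in rng.uniform(*cfg.pause_range, size=len(order)))
    return PairedPulseSchedule(isis=tuple(float(x) for x in np.sort(isis)), order=order, pauses=pauses)


# ---------------------------------------------------------------------------
# Generative gain/latency functions (ground truth for parameter recovery)


def refractory_gain(isi, arp: float, rrp: float):
    """Test-response gain: 0 through the ARP, exponential recovery after.

    The recovery constant is tied to the RRP so that gain(rrp) = 0.98,
    the same threshold the estimator uses on the analysis side.
    """
    if not 0 < arp < rrp:
        raise SimulationError(f"need 0 < arp < rrp, got {arp}, {rrp}")
    isi = np.asarray(isi, dtype=float)
    tau = (rrp - arp) / np.log(50.0)
    gain = np.where(isi <= arp, 0.0, -np.expm1(-np.maximum(isi - arp, 0.0) / tau))
    return gain if gain.ndim else float(gain)


def latency_delay(isi, cfg: SimConfig):
    """Extra R1 latency (ms) inside the relative refractory period."""
    isi = np.asarray(isi, dtype=float)
    d = cfg.latency_delay_max * np.exp(-(isi - cfg.arp) / cfg.latency_delay_tau)
    return d if d.ndim else float(d)


def facilitation_gain(isi, cfg: SimConfig):
    """ERNA gain: Gaussian facilitation bumps on top of refractory recovery."""
    isi = np.asarray(isi, dtype=float)
    bump = np.ones_like(isi)
    for center, width, gain in cfg.facil_bands:
        bump = bump + gain * np.exp(-((isi - center) ** 2) / (2.0 * width**2))
    out = bump * refractory_gain(isi, cfg.arp, cfg.rrp)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Waveform kernels


def artifact_kernel(t_ms: np.ndarray, cfg: SimConfig, polarity: int) -> np.ndarray:
    """Polarity-locked exponential transient, truncated at 0.1 ms."""
    k = np.zeros_like(t_ms)
    m = (t_ms >= 0.0) & (t_ms <= 0.1)
    k[m] = polarity * cfg.artifact_amp * np.exp(-t_ms[m] / cfg.artifact_decay)
    return k


_DOG_CACHE: dict[tuple, tuple[float, float, float, float, float, float]] = {}


def r1_dog_params(cfg: SimConfig) -> tuple[float, float, float, float, float, float]:
    """Difference-of-Gaussians parameters with extrema exactly at the
    configured (peak_lat, peak_amp) and (trough_lat, -trough_amp).

    Widths are fixed fractions of the peak-trough separation; the four
    free parameters (two amplitudes, two centers) are solved so that the
    *sum* has its analytic extrema at the requested points, which makes
    detector tests exact rather than approximate.
    """
    key = (cfg.r1_peak_amp, cfg.r1_peak_lat, cfg.r1_trough_amp, cfg.r1_trough_lat)
    if key in _DOG_CACHE:
        return _DOG_CACHE[key]
    sep = cfg.r1_trough_lat - cfg.r1_peak_lat
    if sep <= 0:
        raise SimulationError("r1_trough_lat must exceed r1_peak_lat")
    # narrow peak: keeps the rising flank's mass above the post-stimulus
    # blanking interval even when the response is latency-delayed
    s1, s2 = 0.2 * sep, 0.45 * sep

    def f(t, a, b, m1, m2):
        return a * np.exp(-((t - m1) ** 2) / (2 * s1**2)) - b * np.exp(
            -((t - m2) ** 2) / (2 * s2**2)
        )

    def fprime(t, a, b, m1, m2):
        return -a * (t - m1) / s1**2 * np.exp(-((t - m1) ** 2) / (2 * s1**2)) + b * (
            t - m2
        ) / s2**2 * np.exp(-((t - m2) ** 2) / (2 * s2**2))

    tp, tt = cfg.r1_peak_lat, cfg.r1_trough_lat
    ap, at = cfg.r1_peak_amp, cfg.r1_trough_amp

    def residual(x):
        a, b, m1, m2 = x
        return [
            f(tp, a, b, m1, m2) - ap,
            fprime(tp, a, b, m1, m2),
            f(tt, a, b, m1, m2) + at,
            fprime(tt, a, b, m1, m2),
        ]

    x0 = np.array([ap, at, tp, tt])
    sol, info, ier, msg = fsolve(residual, x0, full_output=True)
    if ier != 1 or np.max(np.abs(residual(sol))) > 1e-10:
        raise SimulationError(f"R1 kernel calibration failed: {msg}")
    params = (float(sol[0]), float(sol[1]), float(sol[2]), float(sol[3]), s1, s2)
    _DOG_CACHE[key] = params
    return params


def r1_kernel(t_ms: np.ndarray, cfg: SimConfig, gain: float = 1.0, delay: float = 0.0) -> np.ndarray:
    a, b, m1, m2, s1, s2 = r1_dog_params(cfg)
    t = t_ms - delay
    return gain * (
        a * np.exp(-((t - m1) ** 2) / (2 * s1**2))
        - b * np.exp(-((t - m2) ** 2) / (2 * s2**2))
    )


def erna_kernel(
    t_ms: np.ndarray, cfg: SimConfig, gain: float = 1.0, onset_shift: float = 0.0
) -> np.ndarray:
    """Damped sinusoid starting at ``erna_onset + onset_shift``."""
    onset = cfg.erna_onset + onset_shift
    u = t_ms - onset
    k = np.zeros_like(t_ms)
    m = u >= 0.0
    k[m] = (
        gain
        * cfg.erna_amp
        * np.sin(2 * np.pi * cfg.erna_freq * u[m] / 1000.0)
        * np.exp(-u[m] / cfg.erna_decay)
    )
    return k


def erna_first_peak_latency(cfg: SimConfig) -> float:
    """Analytic latency (ms) of the kernel's first oscillation maximum."""
    w = 2 * np.pi * cfg.erna_freq / 1000.0  # rad per ms
    return cfg.erna_onset + np.arctan(w * cfg.erna_decay) / w


def erna_channel_scales(cfg: SimConfig) -> np.ndarray:
    """Per-channel ERNA scaling tied to the beta amplitude gradient.

    Sign of corr(beta amplitude, ERNA scale) across channels equals
    sign(beta_erna_coupling); with zero coupling all scales are 1.
    """
    beta = np.asarray(cfg.beta_amp_per_channel, dtype=float)
    if cfg.beta_erna_coupling == 0.0 or np.ptp(beta) == 0.0:
        return np.ones_like(beta)
    centered = (beta - beta.mean()) / np.ptp(beta)
    return np.clip(1.0 + cfg.beta_erna_coupling * centered, 0.05, None)


# ---------------------------------------------------------------------------
# Session synthesis

_KERNEL_SPAN_MS = 20.0  # evoked content evaluated this far past each pulse


def synthesize_session(cfg: SimConfig) -> tuple[TimeSeriesRecording, dict]:
    """Generate a full paired-pulse session and its ground-truth record."""
    cfg.validate()
    fs = cfg.sample_rate
    schedule = build_schedule(cfg)
    rng = np.random.default_rng(cfg.seed)
    rng_noise = np.random.default_rng((cfg.seed, 0xBEEF))

    # --- event layout (sample-aligned conditioning onsets) ----------------
    tail_s = 0.05
    lead_s = 0.05  # baseline before the first pulse, past any rest prologue
    t = cfg.rest_duration + lead_s
    pulse_plan: list[tuple[int, float, int, str, float, int]] = []  # sample,isi,pol,role,isi,pair
    events: list[StimEvent] = []
    for pair_id, ((isi, pol), pause) in enumerate(zip(schedule.order, schedule.pauses)):
        i_cond = int(round(t * fs))
        i_test = i_cond + int(round(isi * fs / 1000.0))
        events.append(
            StimEvent(time=i_cond / fs, polarity=pol, pair_id=pair_id,
                      pulse_role="conditioning", isi=isi, channel_set="C0-C1")
        )
        events.append(
            StimEvent(time=i_test / fs, polarity=pol, pair_id=pair_id,
                      pulse_role="test", isi=isi, channel_set="C0-C1")
        )
        pulse_plan.append((i_cond, i_test, pol, isi, pair_id))
        t = i_test / fs + pause / 1000.0
    n = int(round((t + tail_s) * fs))
    last_needed = int(round(events[-1].time * fs)) + int(round(_KERNEL_SPAN_MS * fs / 1000.0))
    if last_needed >= n:
        raise SimulationError("pulse train overlaps the recording end")

    # --- component traces shared across recording channels ----------------
    span = int(round(_KERNEL_SPAN_MS * fs / 1000.0))
    t_local = np.arange(span) / fs * 1000.0  # ms since pulse onset
    artifact_tr = np.zeros(n)
    r1_tr = np.zeros(n)
    erna_tr = np.zeros(n)

    for i_cond, i_test, pol, isi, _pid in pulse_plan:
        art = artifact_kernel(t_local, cfg, pol)
        artifact_tr[i_cond : i_cond + span] += art
        artifact_tr[i_test : i_test + span] += art
        r1c = r1_kernel(t_local, cfg)
        r1_tr[i_cond : i_cond + span] += r1c
        g = refractory_gain(isi, cfg.arp, cfg.rrp)
        if g > 0.0:
            r1_tr[i_test : i_test + span] += r1_kernel(
                t_local, cfg, gain=g, delay=latency_delay(isi, cfg)
            )
        if cfg.erna_present:
            erna_tr[i_cond : i_cond + span] += erna_kernel(t_local, cfg)
            fg = facilitation_gain(isi, cfg)
            if fg > 0.0:
                erna_tr[i_test : i_test + span] += erna_kernel(
                    t_local, cfg, gain=fg, onset_shift=-cfg.hasten_per_gain * (fg - 1.0)
                )

    # --- per-channel assembly ---------------------------------------------
    n_rec = cfg.n_record_channels
    erna_scale = erna_channel_scales(cfg)
    t_s = np.arange(n) / fs
    channels: list[ChannelInfo] = [
        ChannelInfo(label="C0", role=ChannelRole.STIM_ANODE, row=0),
        ChannelInfo(label="C1", role=ChannelRole.STIM_CATHODE, row=1),
    ]
    signals = np.zeros((2 + n_rec, n))
    rec_role = ChannelRole.RING_RECORD if n_rec <= 2 else ChannelRole.SEGMENT_RECORD
    for c in range(n_rec):
        label = f"C{c + 2}" if n_rec <= 2 else f"S{c + 1}"
        channels.append(ChannelInfo(label=label, role=rec_role, row=c + 2))
        x = (
            cfg.channel_artifact_gain[c] * artifact_tr
            + cfg.channel_response_gain[c] * (r1_tr + erna_scale[c] * erna_tr)
        )
        phase = rng.uniform(0, 2 * np.pi)
        x = x + cfg.beta_amp_per_channel[c] * np.sin(2 * np.pi * cfg.beta_freq * t_s + phase)
        if cfg.pink_noise_amp > 0.0:
            x = x + cfg.pink_noise_amp * _pink_noise(n, rng_noise)
        if cfg.noise_sd > 0.0:
            x = x + rng_noise.normal(0.0, cfg.noise_sd, size=n)
        signals[2 + c] = x

    rec = TimeSeriesRecording(
        sample_rate=fs,
        signals=signals,
        channels=channels,
        events=events,
        meta={"generator": "ppdbs.simulate", "seed": cfg.seed},
    )
    rec.validate()

    isis = np.asarray(schedule.isis)
    arp_rule, rrp_rule = rule_refractory_bounds(cfg)
    truth = {
        "config": asdict(cfg),
        "isis_ms": isis.tolist(),
        "arp_rule_ms": arp_rule,
        "rrp_rule_ms": rrp_rule,
        "refractory_gain": refractory_gain(isis, cfg.arp, cfg.rrp).tolist(),
        "facilitation_gain": facilitation_gain(isis, cfg).tolist() if cfg.erna_present else None,
        "latency_delay_ms": latency_delay(isis, cfg).tolist(),
        "erna_channel_scale": erna_scale.tolist(),
        "erna_first_peak_latency_ms": erna_first_peak_latency(cfg) if cfg.erna_present else None,
        "schedule_order": [[isi, pol] for isi, pol in schedule.order],
    }
    return rec, truth


def rule_refractory_bounds(
    cfg: SimConfig,
    arp_threshold: float = 0.2,
    rrp_threshold: float = 0.98,
    run: int = 3,
) -> tuple[float | None, float | None]:
    """Refractory-period values the run-of-3 scan rules yield on the *true*
    R1 gain curve sampled at the short-ISI grid.

    This is the correct recovery target for the estimators: the scan
    rules locate the threshold crossings of the gain curve, which for
    the exponential recovery form sit above ``cfg.arp`` (the 0.2
    crossing is at arp + tau*ln(1.25)) and exactly at ``cfg.rrp`` (by
    the tau definition, gain(rrp) = 0.98).
    """
    short = np.geomspace(*cfg.isi_short_range, cfg.n_short_isi)
    gain = refractory_gain(short, cfg.arp, cfg.rrp)
    arp_rule = None
    streak = 0
    for i in range(len(short) - 1, -1, -1):
        streak = streak + 1 if gain[i] < arp_threshold else 0
        if streak == run:
            arp_rule = float(short[i + run - 1])
            break
    rrp_rule = None
    streak = 0
    for i in range(len(short)):
        streak = streak + 1 if gain[i] > rrp_threshold else 0
        if streak == run:
            rrp_rule = float(short[i - run + 1])
            break
    return arp_rule, rrp_rule


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def write_session(cfg: SimConfig, out_dir: str | Path) -> dict:
    """Materialize a session as EDF + events CSV + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, truth = synthesize_session(cfg)
    write_recording(rec, out / "session.edf", out / "events.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


__all__ = [
    "PairedPulseSchedule",
    "SimConfig",
    "SimulationError",
    "artifact_kernel",
    "build_schedule",
    "erna_first_peak_latency",
    "erna_kernel",
    "facilitation_gain",
    "latency_delay",
    "r1_dog_params",
    "r1_kernel",
    "refractory_gain",
    "synthesize_session",
    "write_session",
]
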