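"""Synthetic hemodynamics with known baroreflex gain.

The generator produces beat-by-beat ground truth and, on request, rendered
ECG/pulse waveforms. The mechanism is deliberately open loop so the true
transfer gain from systolic pressure to heart period is known analytically:

* systolic pressure carries a low-frequency (Mayer-wave, ~0.1 Hz) and a
  high-frequency (respiratory, ~0.25 Hz) oscillation on a slowly varying
  baseline;
* the heart period responds to the delayed pressure deviation with a fixed
  gain in ms/mmHg — the quantity the spectral estimator must recover;
* pulse arrival time and the rise/decay-time ratio are inversely coupled to
  systolic pressure, mimicking the stiffening of arteries under pressure;
* a circadian profile scales gain, pressure and heart period piecewise to
  emulate sleep, office work and walks; cuff inflations and motion-artifact
  bursts are scheduled as events.

Rendered pulses are asymmetric two-Gaussian waves: a primary peak whose
rising and falling widths independently realise the requested rise/decay
ratio, plus a small late dicrotic bump. The pulse upstroke (maximum of the
first derivative) is placed exactly at R + PAT so that feature extraction
inverts the generator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .signal_io import Event, EventList, MultiChannelRecord

#: Threshold-crossing constant linking an asymmetric-Gaussian half-width to
#: the 10%→70% (rise) or 70%→10% (decay) crossing time: sqrt(2 ln 10) − sqrt(2 ln(10/7)).
_CROSS = math.sqrt(2 * math.log(10.0)) - math.sqrt(2 * math.log(10.0 / 7.0))


@dataclass
class CircadianSegment:
    """Piecewise multiplier block of the 24-h profile."""

    start_s: float
    end_s: float
    gain_mult: float = 1.0
    sbp_mult: float = 1.0
    rr_mult: float = 1.0
    label: str = ""


@dataclass
class SimConfig:
    """Generator parameters. Defaults describe a resting adult.

    Couplings follow the study conditions: ~0.1 Hz pressure oscillations of a
    few mmHg drive the heart period with a gain of 8 ms/mmHg (a healthy
    middle-aged value), pulse arrival time shortens by ~1 ms per mmHg, and
    the rise/decay ratio falls slightly as pressure rises.
    """

    duration_s: float = 300.0
    fs: float = 240.0                       # waveform rendering rate, Hz

    baseline_sbp: float = 120.0             # mmHg
    lf_amp: float = 3.0                     # mmHg at lf_freq
    lf_freq: float = 0.1                    # Hz (Mayer wave)
    hf_amp: float = 1.5                     # mmHg at hf_freq
    hf_freq: float = 0.25                   # Hz (respiration)
    sbp_noise_sd: float = 1.0               # mmHg, beat-to-beat (drives the reflex)

    gain_ms_per_mmhg: float = 8.0           # true BRS
    reflex_delay_beats: int = 1
    rr_baseline_ms: float = 1000.0
    rr_noise_sd_ms: float = 10.0

    # coupling noise calibrated so beat-level corr(PAT, SBP) ~ -0.9 and
    # corr(RDRatio, SBP) ~ -0.6, the magnitudes seen in ambulatory data
    pat_intercept_ms: float = 250.0
    pat_slope_ms_per_mmhg: float = -1.0     # inverse coupling
    pat_noise_sd_ms: float = 1.2

    rdr_intercept: float = 1.0
    rdr_slope_per_mmhg: float = -0.005      # inverse coupling
    rdr_noise_sd: float = 0.016

    diastolic_mmhg: float = 80.0            # rendered pressure-pulse baseline
    rise_decay_total_s: float = 0.30        # rise + decay time of the rendered pulse
    dicrotic_rel_amp: float = 0.12
    measurement_noise_sd: dict = field(
        default_factory=lambda: {"ECG": 0.0, "PPG": 0.0, "ABP": 0.0, "VCP": 0.0}
    )

    artifact_intervals: tuple = ()          # ((start_s, end_s), ...) motion bursts
    cuff_times: tuple = ()                  # inflation start times, s
    cuff_duration_s: float = 30.0
    circadian: tuple = ()                   # CircadianSegment sequence
    seed: int = 0

    def validate(self):
        if not (self.duration_s > 0 and self.fs > 0 and self.gain_ms_per_mmhg > 0):
            raise ConfigurationError("duration, fs and gain must be positive")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ConfigurationError("lf_freq must lie in the LF band (0.04-0.15 Hz)")
        # respiration sits in the HF band at rest but paced breathing can
        # legitimately move it into the LF band (e.g. 7 breaths/min)
        if not 0.05 <= self.hf_freq <= 0.50:
            raise ConfigurationError("hf_freq must lie in the breathing range (0.05-0.50 Hz)")


@dataclass
class SimGroundTruth:
    """Pre-noise-free record of what the generator actually did, per beat."""

    beat_times: np.ndarray      # s, R-peak times
    sbp: np.ndarray             # mmHg, true systolic pressure per beat
    rr_ms: np.ndarray           # ms, heart period of beat n (t_{n+1} - t_n)
    pat_ms: np.ndarray          # ms, R-to-upstroke delay
    rdratio: np.ndarray         # dimensionless
    true_gain: np.ndarray       # ms/mmHg effective gain at each beat
    events: EventList
    config: SimConfig

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


def _circadian_at(circadian: Sequence[CircadianSegment], t: float):
    g = s = r = 1.0
    for seg in circadian:
        if seg.start_s <= t < seg.end_s:
            g *= seg.gain_mult
            s *= seg.sbp_mult
            r *= seg.rr_mult
    return g, s, r


def simulate_beats(cfg: SimConfig) -> SimGroundTruth:
    """Generate the beat-level ground-truth series.

    Beat times accumulate from the heart period, which responds to the
    pressure deviation ``reflex_delay_beats`` earlier:

        SBP_n = baseline·c_sbp(t_n) + LF + HF + noise
        RR_n  = rr_baseline·c_rr(t_n) + gain·c_gain(t_n)·(SBP_{n-d} − baseline_{n-d}) + noise

    With zero noise the least-squares slope of RR on the lagged pressure
    deviation equals the configured gain exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    d = int(cfg.reflex_delay_beats)

    times, sbps, sbp_devs, rrs, gains = [], [], [], [], []
    t = 0.4  # the record opens mid-cycle: first R arrives after a diastole
    n = 0
    while t < cfg.duration_s:
        g_m, s_m, r_m = _circadian_at(cfg.circadian, t)
        base = cfg.baseline_sbp * s_m
        sbp = (
            base
            + cfg.lf_amp * math.sin(2 * math.pi * cfg.lf_freq * t)
            + cfg.hf_amp * math.sin(2 * math.pi * cfg.hf_freq * t)
            + (rng.normal(0.0, cfg.sbp_noise_sd) if cfg.sbp_noise_sd > 0 else 0.0)
        )
        dev = sbp_devs[n - d] if n >= d else 0.0
        gain = cfg.gain_ms_per_mmhg * g_m
        rr = cfg.rr_baseline_ms * r_m + gain * dev + (
            rng.normal(0.0, cfg.rr_noise_sd_ms) if cfg.rr_noise_sd_ms > 0 else 0.0
        )
        if rr <= 300.0:
            raise ValidationError(
                f"nonphysiologic: configuration yields RR = {rr:.0f} ms at t = {t:.1f} s"
            )
        times.append(t)
        sbps.append(sbp)
        sbp_devs.append(sbp - base)
        rrs.append(rr)
        gains.append(gain)
        t += rr / 1000.0
        n += 1

    times = np.asarray(times)
    sbps = np.asarray(sbps)
    pat = cfg.pat_intercept_ms + cfg.pat_slope_ms_per_mmhg * sbps
    if cfg.pat_noise_sd_ms > 0:
        pat = pat + rng.normal(0.0, cfg.pat_noise_sd_ms, size=pat.size)
    rdr = cfg.rdr_intercept + cfg.rdr_slope_per_mmhg * sbps
    if cfg.rdr_noise_sd > 0:
        rdr = rdr + rng.normal(0.0, cfg.rdr_noise_sd, size=rdr.size)
    # heavy coupling noise may not drive these below their physiologic floors
    pat = np.maximum(pat, 20.0)
    rdr = np.maximum(rdr, 0.05)

    events = [
        Event("cuff_inflation", "cuff", t0, t0 + cfg.cuff_duration_s) for t0 in cfg.cuff_times
    ]
    events += [
        Event("activity", seg.label or "segment", seg.start_s, seg.end_s)
        for seg in cfg.circadian
        if seg.label
    ]
    return SimGroundTruth(
        beat_times=times,
        sbp=sbps,
        rr_ms=np.asarray(rrs),
        pat_ms=pat,
        rdratio=rdr,
        true_gain=np.asarray(gains),
        events=EventList(events=list(events)),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# waveform rendering


def pulse_widths(rdratio: float, total_rd_s: float) -> tuple[float, float]:
    """Rise/decay Gaussian half-widths realising a rise/decay-time ratio.

    For an asymmetric Gaussian the 10%→70% rise time is ``_CROSS · σ_rise``
    and the 70%→10% decay time is ``_CROSS · σ_decay``, so the ratio of the
    half-widths equals the ratio of the crossing times exactly.
    """
    sigma_d = total_rd_s / (_CROSS * (1.0 + rdratio))
    return rdratio * sigma_d, sigma_d


def _add_gaussian(sig: np.ndarray, fs: float, center_s: float, sigma_s: float, amp: float,
                  side: str = "both"):
    half = 5.0 * sigma_s
    i0 = max(0, int((center_s - half) * fs))
    i1 = min(sig.size, int((center_s + half) * fs) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / fs - center_s
    g = amp * np.exp(-0.5 * (tt / sigma_s) ** 2)
    if side == "left":
        g[tt > 0] = 0.0
    elif side == "right":
        g[tt < 0] = 0.0
    sig[i0:i1] += g


def render_signals(
    gt: SimGroundTruth,
    channels: Sequence[str] = ("ECG", "PPG", "ABP"),
    seed: int | None = None,
) -> MultiChannelRecord:
    """Render waveforms from the beat-level ground truth.

    ECG is a train of narrow R spikes (plus small T waves) at the beat
    times. Pulse channels place the maximum-slope point (upstroke) of an
    asymmetric two-Gaussian pulse at R + PAT; the foot-to-peak amplitude
    tracks systolic pressure and the half-widths realise the true rise/decay
    ratio. Scheduled artifact bursts add broadband noise to the PPG;
    cuff inflations flatten the PPG (occlusion).
    """
    cfg = gt.config
    if cfg.fs < 60.0:
        raise ConfigurationError("fs < 60 Hz cannot realise pulse morphology")
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    # a short tail so the final beat's pulse and T wave are never truncated
    n = int(round((cfg.duration_s + 1.2) * cfg.fs))
    out: dict[str, np.ndarray] = {}
    units = {"ECG": "mV", "PPG": "au", "ABP": "mmHg", "VCP": "mmHg"}

    for role in channels:
        sig = np.zeros(n)
        if role == "ECG":
            for t in gt.beat_times:
                _add_gaussian(sig, cfg.fs, t, 0.008, 1.0)          # R spike
                _add_gaussian(sig, cfg.fs, t + 0.25, 0.04, 0.15)   # T wave
        else:
            base = cfg.diastolic_mmhg if role in ("ABP", "VCP") else 0.0
            sig += base
            for tb, sbp, pat, rdr in zip(
                gt.beat_times, gt.sbp, gt.pat_ms, gt.rdratio, strict=True
            ):
                s_r, s_d = pulse_widths(float(rdr), cfg.rise_decay_total_s)
                amp = (sbp - base) if role in ("ABP", "VCP") else sbp / cfg.baseline_sbp
                tp = tb + pat / 1000.0 + s_r  # upstroke (max slope) at R + PAT
                _add_gaussian(sig, cfg.fs, tp, s_r, amp, side="left")
                _add_gaussian(sig, cfg.fs, tp, s_d, amp, side="right")
                _add_gaussian(sig, cfg.fs, tp + 3.5 * s_d, 0.4 * s_d,
                              cfg.dicrotic_rel_amp * amp)
        noise_sd = cfg.measurement_noise_sd.get(role, 0.0)
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, size=n)
        if role == "PPG":
            tgrid = np.arange(n) / cfg.fs
            for a0, a1 in cfg.artifact_intervals:
                m = (tgrid >= a0) & (tgrid < a1)
                sig[m] += rng.normal(0.0, 3.0, size=int(m.sum()))
            for ev in gt.events.of_kind("cuff_inflation"):
                m = (tgrid >= ev.start) & (tgrid < ev.end)
                sig[m] = 0.0
        out[role] = sig

    return MultiChannelRecord(
        channels=out,
        fs={r: cfg.fs for r in out},
        units={r: units.get(r, "au") for r in out},
    )


# ---------------------------------------------------------------------------
# study-shaped scenarios


#: Intervention presets: multiplicative changes applied to the resting
#: configuration. Gain deltas follow the interventional observations
#: (+11% under paced breathing, −22% under sustained handgrip); paced
#: breathing at 7 breaths/min moves the respiratory peak into the LF band.
INTERVENTIONS = {
    "rest": dict(duration_s=120.0),
    "paced_breathing": dict(duration_s=180.0, gain_mult=1.11, hf_freq=7.0 / 60.0, hf_amp_mult=2.0),
    "handgrip": dict(duration_s=90.0, gain_mult=0.78, sbp_mult=1.08),
}


def trial_config(base: SimConfig, intervention: str, seed: int) -> SimConfig:
    """Resting config adjusted for one intervention trial."""
    try:
        p = INTERVENTIONS[intervention]
    except KeyError:
        raise ConfigurationError(f"unknown intervention {intervention!r}") from None
    return replace(
        base,
        duration_s=p.get("duration_s", base.duration_s),
        gain_ms_per_mmhg=base.gain_ms_per_mmhg * p.get("gain_mult", 1.0),
        baseline_sbp=base.baseline_sbp * p.get("sbp_mult", 1.0),
        hf_freq=p.get("hf_freq", base.hf_freq),
        hf_amp=base.hf_amp * p.get("hf_amp_mult", 1.0),
        seed=seed,
    )


@dataclass
class Trial:
    """One simulated session × intervention of one virtual participant."""

    participant: int
    session: int
    intervention: str
    truth: SimGroundTruth


def simulate_cohort(
    n_participants: int = 28,
    n_sessions: int = 3,
    interventions: Sequence[str] = ("rest", "paced_breathing", "handgrip"),
    gain_range: tuple[float, float] = (4.0, 12.0),
    coupling_noise_scale: float = 1.0,
    seed: int = 0,
    base: SimConfig | None = None,
) -> tuple[list[Trial], np.ndarray]:
    """Simulate the interventional cohort: participants × sessions × interventions.

    Per-participant true gains are drawn uniformly from ``gain_range``.
    ``coupling_noise_scale`` multiplies the PAT and rise/decay coupling noise,
    degrading the surrogate indices without touching the reference pressure
    channel. Returns the trials and the array of true gains.
    """
    rng = np.random.default_rng(seed)
    base = base or SimConfig()
    gains = rng.uniform(*gain_range, size=n_participants)
    trials = []
    for p in range(n_participants):
        pcfg = replace(
            base,
            gain_ms_per_mmhg=float(gains[p]),
            pat_noise_sd_ms=base.pat_noise_sd_ms * coupling_noise_scale,
            rdr_noise_sd=base.rdr_noise_sd * coupling_noise_scale,
        )
        for s in range(n_sessions):
            for iv in interventions:
                tseed = int(rng.integers(0, 2**31 - 1))
                trials.append(
                    Trial(p, s, iv, simulate_beats(trial_config(pcfg, iv, tseed)))
                )
    return trials, gains


def qualification_fixture(seed: int = 0):
    """A 1-hour beat-level record with planted quality defects.

    3600 beats at exactly 1 Hz with identical pulse morphology, except:
    one cuff inflation at 1200 s, one minute (1800-1860 s) of pure-noise
    beat waveforms, and two PAT outliers (beats 300 and 400) outside the
    pulse-wave-velocity range. Returns a dict with the series, the beat
    waveforms, the events, and the index sets each criterion must flag —
    derived from the construction, not from running any detector.
    """
    rng = np.random.default_rng(seed)
    n = 3600
    t = 0.5 + np.arange(n, dtype=float)
    rr = np.full(n, 1000.0)
    pat = np.full(n, 150.0)
    pat[300] = 40.0    # implies PWV > 10 m/s at 0.8 m
    pat[400] = 450.0   # implies PWV < 2 m/s

    tt = np.linspace(0.0, 1.0, 100)
    template = np.exp(-0.5 * ((tt - 0.25) / 0.08) ** 2) + 0.2 * np.exp(
        -0.5 * ((tt - 0.6) / 0.1) ** 2
    )
    waves = [template.copy() for _ in range(n)]
    artifact_beats = set(range(1800, 1860))
    for i in artifact_beats:
        waves[i] = rng.normal(0.0, 1.0, size=100)

    events = EventList(events=[Event("cuff_inflation", "cuff", 1200.0, 1230.0)])
    cuff_beats = {i for i in range(n) if 1200.0 - 15.0 <= t[i] <= 1200.0 + 60.0}
    return {
        "beat_times": t,
        "rr_ms": rr,
        "pat_ms": pat,
        "waveforms": waves,
        "events": events,
        "expect_cuff": cuff_beats,
        "expect_snr": artifact_beats,
        "expect_pat_range": {300, 400},
        # a PAT jump flags the jumping beat and the return to baseline
        "expect_variability": {300, 301, 400, 401},
        # epoch 20 loses all beats to the cuff window, epoch 30 to the artifact
        "expect_epoch_epochs": {20, 30},
        "ecg_beats_per_epoch": [60] * 60,
    }


def scenario_24h(
    seed: int = 0,
    night_gain_mult: float = 2.0,
    walk_gain_mult: float = 0.6,
    render: bool = False,
    base: SimConfig | None = None,
) -> tuple[MultiChannelRecord | None, EventList, SimGroundTruth]:
    """A 24-hour free-living day starting at midnight.

    Night (00:00–08:00) doubles the baroreflex gain by default and adds a
    slow nocturnal gain oscillation (90-min sleep-cycle alternation); two
    daytime walks raise heart rate and pressure, depress gain, and carry
    motion-artifact bursts. Cuff inflations run every 30 min at night and
    every 15 min during the day (16 + 64 = 80 events).
    """
    h = 3600.0
    night_end = 8 * h
    walks = ((17 * h, 18 * h), (23 * h, 23.25 * h))
    segs = [
        CircadianSegment(0.0, night_end, gain_mult=night_gain_mult,
                         sbp_mult=0.92, rr_mult=1.1, label="sleep"),
    ]
    # nocturnal oscillation: alternate 45-min half-cycles around the night gain
    cyc = 90 * 60.0
    t0 = 0.0
    while t0 < night_end:
        segs.append(CircadianSegment(t0, min(t0 + cyc / 2, night_end), gain_mult=1.15))
        segs.append(CircadianSegment(min(t0 + cyc / 2, night_end),
                                     min(t0 + cyc, night_end), gain_mult=1.0 / 1.15))
        t0 += cyc
    for w0, w1 in walks:
        segs.append(CircadianSegment(w0, w1, gain_mult=walk_gain_mult,
                                     sbp_mult=1.1, rr_mult=0.75, label="walk"))

    cuffs = [t for t in np.arange(0.0, night_end, 30 * 60.0)]
    cuffs += [t for t in np.arange(night_end, 24 * h, 15 * 60.0)]

    cfg = replace(
        base or SimConfig(),
        duration_s=24 * h,
        circadian=tuple(segs),
        cuff_times=tuple(sorted(cuffs)),
        artifact_intervals=tuple((w0 + 600.0, w0 + 660.0) for w0, _ in walks),
        seed=seed,
    )
    gt = simulate_beats(cfg)
    record = render_signals(gt) if render else None
    return record, gt.events, gt
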