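"""Per-beat features: RR, pulse arrival time, amplitudes, and rise/decay ratio.

The feature definitions follow the pulse-contour conventions used for
baroreflex work: PAT is the delay between an ECG R peak and the pulse
upstroke; peak amplitude is foot-referenced for PPG (the "AC" component)
and the absolute systolic value for pressure channels; the rise/decay
ratio compares the 10%→70% systolic rise time to the 70%→10% diastolic
decay time, both referenced to the foot-to-peak amplitude, with
sub-sample threshold crossings by linear interpolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fiducials import FiducialConfig, FiducialSet, detect_pulse_fiducials, detect_r_peaks, preprocess
from .signal_io import MultiChannelRecord

#: Reason codes attached to missing feature values.
REASONS = ("no_pulse", "no_peak", "non_monotone", "no_rr")

PRESSURE_ROLES = ("ABP", "VCP")


def compute_rr(r_peaks) -> np.ndarray:
    """RR interval series in ms; RR_i spans R_i → R_{i+1}.

    Fewer than two peaks yield an empty series.
    """
    r = np.asarray(r_peaks, dtype=float)
    if r.size < 2:
        return np.array([])
    return np.diff(r) * 1000.0


def compute_pat(r_peaks, upstrokes, window_frac: float = 0.8):
    """Pair each R peak with the first pulse upstroke that follows it.

    The pairing window is ``window_frac`` of the current RR interval and
    never extends past the next R peak, preventing cross-beat pairing.
    Returns ``(pat_ms, match_idx)`` aligned to the R peaks; unpaired beats
    hold NaN and match index −1.
    """
    r = np.asarray(r_peaks, dtype=float)
    u = np.asarray(upstrokes, dtype=float)
    if np.any(np.diff(r) < 0) or np.any(np.diff(u) < 0):
        raise ValidationError("R-peak and upstroke lists must be time-ordered")
    pat = np.full(r.size, np.nan)
    match = np.full(r.size, -1, dtype=int)
    for i in range(r.size):
        if i + 1 < r.size:
            limit = r[i] + window_frac * (r[i + 1] - r[i])
            limit = min(limit, r[i + 1])
        else:
            break  # the last beat has no RR to bound the window
        j = np.searchsorted(u, r[i], side="right")
        if j < u.size and u[j] <= limit:
            pat[i] = (u[j] - r[i]) * 1000.0
            match[i] = j
    return pat, match


def _crossing(t, v, level, rising: bool):
    """First sub-sample time where v crosses ``level`` in the given sense."""
    v = np.asarray(v)
    if rising:
        idx = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    else:
        idx = np.nonzero((v[:-1] > level) & (v[1:] <= level))[0]
    if idx.size == 0:
        return None
    i = idx[0]
    dv = v[i + 1] - v[i]
    frac = 0.0 if dv == 0 else (level - v[i]) / dv
    return t[i] + frac * (t[i + 1] - t[i])


def compute_rdratio(
    waveform, fs: float, foot_idx: int, peak_idx: int, end_idx: int,
    lo: float = 0.1, hi: float = 0.7,
):
    """Rise/decay-time ratio of one beat.

    rise = t(70%↑) − t(10%↑) on the systolic limb (foot→peak), decay =
    t(10%↓) − t(70%↓) on the diastolic limb (peak→beat end); both
    thresholds reference the foot-to-peak amplitude. Returns
    ``(ratio, reason)`` with NaN and a reason code when a limb has no
    crossing.
    """
    v = np.asarray(waveform, dtype=float)
    base, top = v[foot_idx], v[peak_idx]
    amp = top - base
    if amp <= 0:
        return np.nan, "no_peak"
    t_sys = np.arange(foot_idx, peak_idx + 1) / fs
    v_sys = v[foot_idx : peak_idx + 1]
    t_dia = np.arange(peak_idx, end_idx) / fs
    v_dia = v[peak_idx:end_idx]
    t10u = _crossing(t_sys, v_sys, base + lo * amp, rising=True)
    t70u = _crossing(t_sys, v_sys, base + hi * amp, rising=True)
    t70d = _crossing(t_dia, v_dia, base + hi * amp, rising=False)
    t10d = _crossing(t_dia, v_dia, base + lo * amp, rising=False)
    if None in (t10u, t70u, t70d, t10d):
        return np.nan, "non_monotone"
    rise = t70u - t10u
    decay = t10d - t70d
    if rise <= 0 or decay <= 0:
        return np.nan, "non_monotone"
    return rise / decay, ""


def compute_amplitude_features(
    waveform, derivative, fs: float, foot_idx: int, peak_idx: int, end_idx: int,
    pressure: bool = False,
):
    """(PeakAmp, Upstroke) of one beat.

    PeakAmp is foot-referenced for PPG-like channels and the absolute
    systolic value for pressure channels (where it *is* SBP). Upstroke is
    the in-beat maximum of the first derivative, in units/s.
    """
    v = np.asarray(waveform, dtype=float)
    if peak_idx is None or not np.isfinite(peak_idx):
        return np.nan, np.nan
    peak_idx = int(peak_idx)
    peakamp = v[peak_idx] if pressure else v[peak_idx] - v[foot_idx]
    upstroke = float(np.max(derivative[foot_idx:max(foot_idx + 1, end_idx)]))
    return peakamp, upstroke


@dataclass
class ChannelFeatures:
    """Beat-aligned features of one pulse channel."""

    role: str
    pat_ms: np.ndarray
    peakamp: np.ndarray
    upstroke: np.ndarray
    rdratio: np.ndarray
    sbp: np.ndarray           # NaN for non-pressure channels
    reasons: list


def extract_channel_features(
    record: MultiChannelRecord, role: str, r_peaks,
    cfg: FiducialConfig | None = None,
    fiducials: FiducialSet | None = None,
) -> ChannelFeatures:
    """Run fiducial detection + all per-beat features for one pulse channel,
    aligned to the ECG R peaks."""
    fs = record.fs[role]
    raw = record.channels[role]
    filt, deriv = preprocess(raw, fs, cfg)
    fid = fiducials if fiducials is not None else detect_pulse_fiducials(raw, fs, cfg)
    pressure = role.split(":")[0] in PRESSURE_ROLES

    r = np.asarray(r_peaks, dtype=float)
    n = r.size
    pat, match = compute_pat(r, fid.upstroke_t)
    peakamp = np.full(n, np.nan)
    upstroke = np.full(n, np.nan)
    rdr = np.full(n, np.nan)
    sbp = np.full(n, np.nan)
    reasons: list[set] = [set() for _ in range(n)]
    for i in range(n):
        b = match[i]
        if b < 0:
            reasons[i].add("no_pulse")
            continue
        foot_i, end_i = fid.bounds[b]
        if not np.isfinite(fid.peak_t[b]):
            reasons[i].add("no_peak")
            continue
        peak_i = int(round(fid.peak_t[b] * fs))
        pa, us = compute_amplitude_features(filt, deriv, fs, foot_i, peak_i, end_i,
                                            pressure=pressure)
        peakamp[i], upstroke[i] = pa, us
        if pressure:
            sbp[i] = pa
        ratio, why = compute_rdratio(filt, fs, foot_i, peak_i, end_i)
        rdr[i] = ratio
        if why:
            reasons[i].add(why)
    return ChannelFeatures(role=role, pat_ms=pat, peakamp=peakamp, upstroke=upstroke,
                           rdratio=rdr, sbp=sbp, reasons=reasons)


def extract_beat_table(
    record: MultiChannelRecord,
    ecg_role: str = "ECG",
    pulse_roles: tuple = ("PPG",),
    cfg: FiducialConfig | None = None,
) -> pd.DataFrame:
    """End-to-end beat table: one row per detected R peak.

    Columns: ``t`` (s), ``RR`` (ms), then per pulse channel ``PAT_<role>``,
    ``PeakAmp_<role>``, ``Upstroke_<role>``, ``RDRatio_<role>``,
    ``SBP_<role>`` (pressure channels only) and ``flags_<role>``
    (';'-joined reason codes). Every feature column has exactly one slot
    per beat — a value or NaN with a reason.
    """
    r = detect_r_peaks(record.channels[ecg_role], record.fs[ecg_role], cfg)
    out = {"t": r}
    rr = compute_rr(r)
    out["RR"] = np.append(rr, np.nan) if r.size else np.array([])
    for role in pulse_roles:
        ch = extract_channel_features(record, role, r, cfg)
        out[f"PAT_{role}"] = ch.pat_ms
        out[f"PeakAmp_{role}"] = ch.peakamp
        out[f"Upstroke_{role}"] = ch.upstroke
        out[f"RDRatio_{role}"] = ch.rdratio
        if role.split(":")[0] in PRESSURE_ROLES:
            out[f"SBP_{role}"] = ch.sbp
        out[f"flags_{role}"] = [";".join(sorted(s)) for s in ch.reasons]
    return pd.DataFrame(out)
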