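"""The five ambulatory (dis)qualification criteria.

Beats are flagged, never deleted: every criterion returns a mask with
machine-readable reason codes, masks combine by union, and each filter is
idempotent. Criteria 1-4 (cuff blanking, template SNR, PAT range,
beat-to-beat variability) commute; the epoch criterion integrates them and
is applied last by contract.

The template-SNR criterion is an open reimplementation of the idea behind
proprietary wearable quality indices: a reference morphology is the
pointwise median of 5 consecutive time-normalised beats and the noise is
each beat's deviation from it. Thresholds here are package defaults, not
values from any device vendor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .signal_io import EventList

REASON_CODES = ("cuff", "snr", "pat_range", "variability", "epoch")


@dataclass
class QualityConfig:
    cuff_pre_s: float = 15.0
    cuff_post_s: float = 60.0
    template_beats: int = 5
    snr_threshold_db: float = 5.0     # empirical package default: clean
    # physiologic beats score > ~17 dB against their template while
    # uncorrelated noise stays below ~5 dB, so 5 dB splits the populations
    template_points: int = 100        # foot-to-foot time normalisation
    path_length_m: float = 0.8
    pwv_min: float = 2.0              # m/s
    pwv_max: float = 10.0             # m/s
    max_rel_delta_rr: float = 0.25
    max_rel_delta_pat: float = 0.25
    epoch_s: float = 60.0
    min_beat_fraction: float = 0.5

    def __post_init__(self):
        if self.pwv_min >= self.pwv_max:
            raise ConfigurationError("pwv_min must be < pwv_max")
        if not 0 < self.min_beat_fraction <= 1:
            raise ConfigurationError("min_beat_fraction must be in (0, 1]")
        for name in ("cuff_pre_s", "cuff_post_s", "template_beats", "path_length_m",
                     "max_rel_delta_rr", "max_rel_delta_pat", "epoch_s"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def pat_valid_range_ms(self) -> tuple[float, float]:
        """Physiologic PAT bounds from a fixed path length and PWV in [2, 10] m/s."""
        return (1000.0 * self.path_length_m / self.pwv_max,
                1000.0 * self.path_length_m / self.pwv_min)


@dataclass
class QualityMask:
    """Per-beat qualification with reason codes; qualified ⇔ no reasons."""

    reasons: list = field(default_factory=list)  # list of sets

    @property
    def qualified(self) -> np.ndarray:
        return np.array([len(r) == 0 for r in self.reasons], dtype=bool)

    @property
    def n(self) -> int:
        return len(self.reasons)

    def merge(self, other: "QualityMask") -> "QualityMask":
        if other.n != self.n:
            raise ValueError("mask lengths differ")
        return QualityMask([a | b for a, b in zip(self.reasons, other.reasons)])

    @classmethod
    def clean(cls, n: int) -> "QualityMask":
        return cls([set() for _ in range(n)])


def blank_cuff(beat_times, events: EventList, cfg: QualityConfig | None = None) -> QualityMask:
    """Flag beats within [start − 15 s, start + 60 s] of each cuff inflation.

    Occlusion of the finger during (and its hemodynamic shadow after) a cuff
    measurement invalidates the PPG; overlapping windows blank their union.
    """
    cfg = cfg or QualityConfig()
    t = np.asarray(beat_times, dtype=float)
    mask = QualityMask.clean(t.size)
    for ev in events.of_kind("cuff_inflation"):
        hit = (t >= ev.start - cfg.cuff_pre_s) & (t <= ev.start + cfg.cuff_post_s)
        for i in np.nonzero(hit)[0]:
            mask.reasons[i].add("cuff")
    return mask


def _normalise_beat(beat, n_points: int):
    """Resample one beat to a fixed grid and normalise offset and amplitude."""
    beat = np.asarray(beat, dtype=float)
    x = np.linspace(0.0, 1.0, beat.size)
    g = np.linspace(0.0, 1.0, n_points)
    y = np.interp(g, x, beat)
    y = y - y[0]
    scale = np.max(np.abs(y))
    return y / scale if scale > 0 else y


def template_snr(beat_waveforms, cfg: QualityConfig | None = None):
    """Template-deviation SNR per beat, in dB, plus the resulting mask.

    Each beat is resampled to ``template_points`` samples foot-to-foot and
    normalised; the reference template for beat *i* is the pointwise median
    of the 5 consecutive beats centred on it (clipped at the record edges).
    SNR_i = 10·log10(template power / residual power). The median template
    tolerates a single outlying beat in the window, so isolated artifacts
    flag only themselves.
    """
    cfg = cfg or QualityConfig()
    n = len(beat_waveforms)
    mask = QualityMask.clean(n)
    if n < cfg.template_beats:
        warnings.warn(f"fewer than {cfg.template_beats} beats: all flagged 'snr'", stacklevel=2)
        for r in mask.reasons:
            r.add("snr")
        return np.full(n, -np.inf), mask
    norm = np.vstack([_normalise_beat(b, cfg.template_points) for b in beat_waveforms])
    half = cfg.template_beats // 2
    snr = np.empty(n)
    for i in range(n):
        lo = min(max(0, i - half), n - cfg.template_beats)
        template = np.median(norm[lo : lo + cfg.template_beats], axis=0)
        resid = norm[i] - template
        p_t = float(np.mean(template**2))
        p_r = float(np.mean(resid**2))
        if p_r == 0:
            snr[i] = np.inf
        elif p_t == 0:
            snr[i] = -np.inf
        else:
            snr[i] = 10.0 * np.log10(p_t / p_r)
        if snr[i] < cfg.snr_threshold_db:
            mask.reasons[i].add("snr")
    return snr, mask


def pat_range_filter(pat_ms, cfg: QualityConfig | None = None) -> QualityMask:
    """Flag PAT values outside the physiologic pulse-wave-velocity window."""
    cfg = cfg or QualityConfig()
    lo, hi = cfg.pat_valid_range_ms
    pat = np.asarray(pat_ms, dtype=float)
    mask = QualityMask.clean(pat.size)
    bad = np.isfinite(pat) & ((pat < lo) | (pat > hi))
    for i in np.nonzero(bad)[0]:
        mask.reasons[i].add("pat_range")
    return mask


def variability_filter(rr_ms, pat_ms=None, cfg: QualityConfig | None = None) -> QualityMask:
    """Flag drastic beat-to-beat jumps in RR and PAT.

    Beat *i* is flagged when its relative change from beat *i−1* exceeds
    the configured fraction; the first beat has no predecessor and is
    never flagged.
    """
    cfg = cfg or QualityConfig()
    rr = np.asarray(rr_ms, dtype=float)
    mask = QualityMask.clean(rr.size)
    series = [(rr, cfg.max_rel_delta_rr)]
    if pat_ms is not None:
        series.append((np.asarray(pat_ms, dtype=float), cfg.max_rel_delta_pat))
    for x, thr in series:
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(np.diff(x)) / np.abs(x[:-1])
        for i in np.nonzero(rel > thr)[0]:
            mask.reasons[i + 1].add("variability")
    return mask


def epoch_qualify(
    beat_times, mask: QualityMask, ecg_beats_per_epoch, cfg: QualityConfig | None = None,
    t0: float = 0.0,
) -> QualityMask:
    """Disqualify whole 1-minute epochs of persistent low quality.

    The ECG defines the expected cardiac-cycle count per epoch; when fewer
    than half (``min_beat_fraction``, inclusive) of those cycles have a
    qualified pulse beat, every beat in the epoch is flagged "epoch". An
    epoch claiming zero ECG beats is disqualified with a warning.
    """
    cfg = cfg or QualityConfig()
    t = np.asarray(beat_times, dtype=float)
    out = QualityMask([set(r) for r in mask.reasons])
    qualified = mask.qualified
    n_epochs = len(ecg_beats_per_epoch)
    for e in range(n_epochs):
        lo, hi = t0 + e * cfg.epoch_s, t0 + (e + 1) * cfg.epoch_s
        in_epoch = (t >= lo) & (t < hi)
        expected = ecg_beats_per_epoch[e]
        if expected == 0:
            warnings.warn(f"epoch {e}: zero ECG beats, disqualified", stacklevel=2)
            frac = 0.0
        else:
            frac = np.count_nonzero(in_epoch & qualified) / expected
        if frac < cfg.min_beat_fraction:
            for i in np.nonzero(in_epoch)[0]:
                out.reasons[i].add("epoch")
    return out


def qualify_beats(
    beat_times, rr_ms, pat_ms, events: EventList,
    beat_waveforms=None, ecg_beats_per_epoch=None,
    cfg: QualityConfig | None = None,
) -> QualityMask:
    """Apply all five criteria in order (epoch integration last)."""
    cfg = cfg or QualityConfig()
    mask = blank_cuff(beat_times, events, cfg)
    if beat_waveforms is not None:
        _, m = template_snr(beat_waveforms, cfg)
        mask = mask.merge(m)
    mask = mask.merge(pat_range_filter(pat_ms, cfg))
    mask = mask.merge(variability_filter(rr_ms, pat_ms, cfg))
    if ecg_beats_per_epoch is not None:
        mask = epoch_qualify(beat_times, mask, ecg_beats_per_epoch, cfg)
    return mask
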