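"""Signal conditioning and per-beat fiducial point detection.

All pulse-wave fiducials are located on the first-derivative signal: the
upstroke is the per-beat maximum of the derivative, the foot is found by
adaptive thresholding below the upstroke, and the peak, dicrotic notch and
secondary peak follow from the derivative's zero crossings after the
upstroke. ECG R peaks are detected with a derivative/energy detector with a
200 ms refractory period.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError


@dataclass
class FiducialConfig:
    """Detection constants. The adaptive-threshold fractions are decisions of
    this package, exposed here because the morphology literature publishes no
    universal values."""

    lowpass_hz: float = 10.0
    filter_order: int = 4
    foot_frac: float = 0.2          # derivative fraction bounding the foot search
    upstroke_frac: float = 0.3      # fraction of the typical upstroke height
    min_beat_interval_s: float = 0.33
    max_beat_span_s: float = 2.0    # cap on a single beat's extent
    refractory_s: float = 0.2       # ECG refractory


def preprocess(x, fs: float, cfg: FiducialConfig | None = None):
    """Zero-phase low-pass filter plus first-derivative signal.

    Returns ``(filtered, derivative)``, both the length of the input. The
    derivative is a central finite difference of the filtered signal in
    signal-units per second — functionally the "differentiating high-pass"
    stage of the classical fiducial chain.
    """
    cfg = cfg or FiducialConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("signal must be 1-D")
    if fs <= 2 * cfg.lowpass_hz:
        raise ConfigurationError(
            f"fs = {fs} Hz too low for a {cfg.lowpass_hz} Hz low-pass (need > {2 * cfg.lowpass_hz})"
        )
    sos = sps.butter(cfg.filter_order, cfg.lowpass_hz, btype="low", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    derivative = np.gradient(filtered, 1.0 / fs)
    return filtered, derivative


def lowpass_response(f_hz: float, fs: float, cfg: FiducialConfig | None = None) -> float:
    """Magnitude response of the (forward-backward) low-pass at one frequency."""
    cfg = cfg or FiducialConfig()
    sos = sps.butter(cfg.filter_order, cfg.lowpass_hz, btype="low", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[f_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)  # filtfilt applies the filter twice


def detect_r_peaks(ecg, fs: float, cfg: FiducialConfig | None = None) -> np.ndarray:
    """ECG R-peak times in seconds.

    Derivative-energy detector: band-limit, differentiate, square, integrate
    over 150 ms, threshold adaptively, then refine each detection to the
    local maximum of the band-limited ECG. At least 2 s of signal required.
    An undetectable signal yields an empty array and a warning, not an error.
    """
    cfg = cfg or FiducialConfig()
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 2 * fs:
        raise ValidationError("need at least 2 s of ECG")
    sos = sps.butter(2, [5.0, min(20.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, ecg)
    energy = np.gradient(band) ** 2
    win = max(1, int(0.15 * fs))
    feat = np.convolve(energy, np.ones(win) / win, mode="same")

    scale = np.percentile(feat, 99)
    if scale <= 0 or np.max(feat) < 1e-12 * max(1.0, np.max(np.abs(ecg)) ** 2):
        warnings.warn("no R peaks found (flat or featureless ECG)", stacklevel=2)
        return np.array([])
    locs, _ = sps.find_peaks(feat, height=0.3 * scale, distance=int(cfg.refractory_s * fs))
    if locs.size == 0:
        warnings.warn("no R peaks found", stacklevel=2)
        return np.array([])

    # refine to the R apex on the band-limited signal
    half = int(0.1 * fs)
    peaks = []
    for i in locs:
        lo, hi = max(0, i - half), min(ecg.size, i + half + 1)
        peaks.append(lo + int(np.argmax(band[lo:hi])))
    peaks = np.unique(peaks)
    # enforce the refractory after refinement
    keep = [peaks[0]]
    for p in peaks[1:]:
        if (p - keep[-1]) / fs >= cfg.refractory_s:
            keep.append(p)
        elif band[p] > band[keep[-1]]:
            keep[-1] = p
    keep = np.asarray(keep)
    # a peak hugging the record edge cannot be confirmed as a full QRS
    edge = int(0.1 * fs)
    keep = keep[(keep >= edge) & (keep < ecg.size - edge)]
    return np.array([(p + _parabolic_offset(band, p)) / fs for p in keep])


@dataclass
class FiducialSet:
    """Per-beat fiducial times (s) and the upstroke slope (units/s).

    Absent morphology points are NaN. ``bounds`` holds the [start, end)
    sample indices of each beat segment on the filtered signal, used by the
    feature stage. Within a beat the order foot ≤ upstroke ≤ peak ≤
    shoulder/notch ≤ secondary peak always holds where points are present.
    """

    foot_t: np.ndarray
    upstroke_t: np.ndarray
    peak_t: np.ndarray
    shoulder_t: np.ndarray
    notch_t: np.ndarray
    secondary_peak_t: np.ndarray
    upstroke_slope: np.ndarray
    bounds: np.ndarray  # (n_beats, 2) int sample indices

    @property
    def n_beats(self) -> int:
        return self.upstroke_t.size

    def check(self):
        for arrs in zip(self.foot_t, self.upstroke_t, self.peak_t,
                        self.shoulder_t, self.notch_t, self.secondary_peak_t):
            seq = [v for v in arrs if np.isfinite(v)]
            if any(b < a - 1e-12 for a, b in zip(seq, seq[1:])):
                raise ValidationError(f"fiducial order violated: {arrs}")
        if np.any(np.diff(self.upstroke_t) <= 0):
            raise ValidationError("beats not strictly ordered in time")


def _parabolic_offset(y, i) -> float:
    """Sub-sample offset of a local maximum by parabolic interpolation."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    off = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(off, -0.5, 0.5))


def _zero_cross(d, start, stop, rising):
    """First index in [start, stop) where d crosses zero in the given sense."""
    for i in range(start, min(stop, d.size - 1)):
        if rising and d[i] <= 0 < d[i + 1]:
            return i if abs(d[i]) <= abs(d[i + 1]) else i + 1
        if not rising and d[i] >= 0 > d[i + 1]:
            return i if abs(d[i]) <= abs(d[i + 1]) else i + 1
    return None


def detect_pulse_fiducials(pulse, fs: float, cfg: FiducialConfig | None = None) -> FiducialSet:
    """Detect per-beat fiducials on a pulse waveform (PPG/ABP/VCP).

    The signal is preprocessed internally. Upstrokes are local maxima of
    the derivative above an adaptive fraction of the typical upstroke
    height; the remaining points are located per beat relative to the
    upstroke. Low-quality beats are *not* rejected here — that is the
    quality module's job.
    """
    cfg = cfg or FiducialConfig()
    filt, d = preprocess(pulse, fs, cfg)

    min_dist = max(1, int(cfg.min_beat_interval_s * fs))
    cand, props = sps.find_peaks(d, distance=min_dist, height=0.0)
    if cand.size == 0:
        return _empty_fiducials()
    heights = props["peak_heights"]
    # locally adaptive height floor: each candidate competes against the
    # typical (upper-half median) candidate height within +-10 s, so an
    # amplitude burst in one stretch cannot blind detection elsewhere
    win = int(10.0 * fs)
    keep_mask = np.zeros(cand.size, dtype=bool)
    for k, c in enumerate(cand):
        local = heights[(cand >= c - win) & (cand <= c + win)]
        typical = np.median(local[local >= np.percentile(local, 50)])
        keep_mask[k] = heights[k] >= cfg.upstroke_frac * typical
    ups = cand[keep_mask]
    # drop upstrokes too close to the record edges to carry a foot
    ups = ups[(ups > int(0.05 * fs))]
    if ups.size == 0:
        return _empty_fiducials()

    n = ups.size
    foot = np.full(n, np.nan)
    peak = np.full(n, np.nan)
    shoulder = np.full(n, np.nan)
    notch = np.full(n, np.nan)
    second = np.full(n, np.nan)
    slope = np.full(n, np.nan)
    bounds = np.zeros((n, 2), dtype=int)
    max_span = int(cfg.max_beat_span_s * fs)

    foot_idx = np.full(n, -1, dtype=int)
    for b, u in enumerate(ups):
        slope[b] = d[u]
        # foot: walk back until the derivative drops below foot_frac of the upstroke
        thr = cfg.foot_frac * d[u]
        lo = max(0, u - max_span // 2)
        i = u
        while i > lo and d[i] > thr:
            i -= 1
        foot_idx[b] = i
        foot[b] = i / fs
        # beat end: next beat's foot (filled after the loop) or a capped span
        end = min(filt.size, u + max_span)
        if b + 1 < n:
            end = min(end, int(ups[b + 1]))
        p = _zero_cross(d, u, end, rising=False)
        if p is not None:
            peak[b] = p / fs
            nz = _zero_cross(d, p + 1, end, rising=True)
            if nz is not None:
                notch[b] = nz / fs
                sp = _zero_cross(d, nz + 1, end, rising=False)
                if sp is not None:
                    second[b] = sp / fs
                # shoulder: interior local maximum of the (negative) derivative
                seg = d[p + 1 : nz]
                if seg.size >= 3:
                    locs, _ = sps.find_peaks(seg, prominence=0.02 * max(d[u], 1e-12))
                    locs = locs[seg[locs] < 0]
                    if locs.size:
                        shoulder[b] = (p + 1 + locs[0]) / fs

    for b in range(n):
        end = foot_idx[b + 1] if b + 1 < n else min(filt.size, int(ups[b]) + max_span)
        bounds[b] = (foot_idx[b], end)

    up_t = np.array([(u + _parabolic_offset(d, u)) / fs for u in ups])
    fs_set = FiducialSet(
        foot_t=foot, upstroke_t=up_t, peak_t=peak, shoulder_t=shoulder,
        notch_t=notch, secondary_peak_t=second, upstroke_slope=slope, bounds=bounds,
    )
    fs_set.check()
    return fs_set


def _empty_fiducials() -> FiducialSet:
    z = np.array([])
    return FiducialSet(z, z, z, z, z, z, z, np.zeros((0, 2), dtype=int))
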