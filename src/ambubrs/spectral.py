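"""Transfer-function baroreflex gain, coherence, and HRV band powers.

The estimator is the classical nonparametric cross-spectral method: beat
series are resampled to a uniform 4 Hz grid, linearly detrended, and
Welch-averaged over 120-sample Hann segments with 50% overlap. The
transfer function is

    H(f) = Pxy(f) / Pxx(f)

with the pressure feature (SBP or a surrogate such as PAT or the
rise/decay ratio) as input x and the RR interval as output y. The BRS
index is the mean |H| over the low-frequency band (0.04-0.15 Hz); the
window qualifies when its mean LF magnitude-squared coherence reaches
0.14, the 95%-confidence floor used with this segmentation. Because the
gain is a magnitude, inversely coupled inputs (PAT falls when pressure
rises) still yield positive indices.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ValidationError, WindowRejected


@dataclass
class SpectralConfig:
    resample_fs: float = 4.0
    detrend_order: int = 1            # linear trend removal before Welch
    segment_len: int = 120
    overlap: float = 0.5
    taper: str = "hann"
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)
    coherence_threshold: float = 0.14
    max_gap_s: float = 5.0            # longest beat gap bridged by interpolation

    def __post_init__(self):
        if not 0 <= self.overlap < 1:
            raise ValidationError("overlap must be in [0, 1)")
        if self.segment_len < 16:
            raise ValidationError("segment_len must be >= 16")
        nyq = self.resample_fs / 2
        for lo, hi in (self.lf_band, self.hf_band):
            if not 0 < lo < hi < nyq:
                raise ValidationError("band bounds must lie within (0, fs/2)")

    @property
    def noverlap(self) -> int:
        return int(self.segment_len * self.overlap)


def to_uniform_series(
    beat_times, values, cfg: SpectralConfig | None = None,
    t_start: float | None = None, t_end: float | None = None,
    detrend: bool = True,
):
    """Resample an irregular beat series onto the uniform 4 Hz grid.

    Missing (NaN) values — disqualified beats — are bridged by linear
    interpolation when the surrounding gap is at most ``max_gap_s``;
    longer gaps reject the window (reason ``gap``). Windows with fewer
    than one spectral segment of samples are rejected (``too_short``).
    Returns ``(t_grid, series)``.
    """
    cfg = cfg or SpectralConfig()
    t = np.asarray(beat_times, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    t, v = t[ok], v[ok]
    if t.size < 2:
        raise WindowRejected("too_short", f"{t.size} usable beats")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("beat times must be strictly increasing")
    if np.any(np.diff(t) > cfg.max_gap_s):
        raise WindowRejected("gap", f"beat gap exceeds {cfg.max_gap_s} s")
    lo = t[0] if t_start is None else max(t_start, t[0])
    hi = t[-1] if t_end is None else min(t_end, t[-1])
    dt = 1.0 / cfg.resample_fs
    grid = np.arange(np.ceil(lo / dt) * dt, hi + 1e-9, dt)
    if grid.size < cfg.segment_len:
        raise WindowRejected("too_short", f"{grid.size} samples < {cfg.segment_len}")
    series = np.interp(grid, t, v)
    if detrend and cfg.detrend_order >= 1:
        series = sps.detrend(series, type="linear")
    elif detrend:
        series = series - np.mean(series)
    return grid, series


@dataclass
class TransferEstimate:
    """Welch cross-spectral estimate between one input feature and RR."""

    f: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pxy: np.ndarray       # complex, conj(X)·Y convention
    H: np.ndarray         # complex transfer function Pxy / Pxx
    msc: np.ndarray       # magnitude-squared coherence, clipped to [0, 1]

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.H)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.H)


def estimate_transfer(x, y, cfg: SpectralConfig | None = None) -> TransferEstimate:
    """Welch-averaged auto-/cross-spectra and the transfer function x → y.

    One-sided density spectra over ``segment_len``-sample tapered segments
    with the configured overlap; segment means are removed before
    tapering. Coherence is computed from the *averaged* spectra, so a
    single segment always gives msc = 1.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < cfg.segment_len:
        raise ValidationError(f"need >= {cfg.segment_len} samples, got {x.size}")
    kw = dict(
        fs=cfg.resample_fs, window=cfg.taper, nperseg=cfg.segment_len,
        noverlap=cfg.noverlap, detrend="constant", scaling="density",
        return_onesided=True,
    )
    f, pxx = sps.welch(x, **kw)
    _, pyy = sps.welch(y, **kw)
    _, pxy = sps.csd(x, y, **kw)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(pxx > 0, pxy / pxx, 0.0 + 0.0j)
        msc = np.where(pxx * pyy > 0, np.abs(pxy) ** 2 / (pxx * pyy), 0.0)
    msc = np.clip(msc.real, 0.0, 1.0)
    return TransferEstimate(f=f, Pxx=pxx, Pyy=pyy, Pxy=pxy, H=H, msc=msc)


@dataclass
class BRSIndex:
    """Band-averaged transfer gain with its coherence qualification."""

    value: float              # ms/mmHg for SBP input, ms/ms for PAT, etc.
    mean_lf_coherence: float
    qualified: bool
    window: tuple = (None, None)
    input_feature: str = "SBP"
    modality: str = "ABP"


def band_bins(f, band) -> np.ndarray:
    """Indices of frequency bins inside a closed band (boundary inclusive)."""
    lo, hi = band
    return np.nonzero((f >= lo - 1e-12) & (f <= hi + 1e-12))[0]


def brs_index(
    est: TransferEstimate, cfg: SpectralConfig | None = None,
    input_feature: str = "SBP", modality: str = "ABP",
    window: tuple = (None, None),
) -> BRSIndex:
    """Mean LF gain and coherence of one transfer estimate.

    The gain is averaged over *all* LF bins; the single coherence threshold
    qualifies the whole window rather than masking individual bins.
    """
    cfg = cfg or SpectralConfig()
    bins = band_bins(est.f, cfg.lf_band)
    if bins.size == 0:
        raise WindowRejected("band_unresolved", "no frequency bin in the LF band")
    value = float(np.mean(est.gain[bins]))
    coh = float(np.mean(est.msc[bins]))
    return BRSIndex(
        value=value, mean_lf_coherence=coh,
        qualified=coh >= cfg.coherence_threshold,
        window=window, input_feature=input_feature, modality=modality,
    )


def hrv_band_power(rr_series, band, cfg: SpectralConfig | None = None) -> float:
    """Integral of the RR auto-spectrum over a band, in ms².

    The series must already be uniformly sampled and detrended
    (:func:`to_uniform_series` does both).
    """
    cfg = cfg or SpectralConfig()
    rr = np.asarray(rr_series, dtype=float)
    if rr.size < cfg.segment_len:
        raise ValidationError(f"need >= {cfg.segment_len} samples, got {rr.size}")
    f, pxx = sps.welch(
        rr, fs=cfg.resample_fs, window=cfg.taper, nperseg=cfg.segment_len,
        noverlap=cfg.noverlap, detrend="constant", scaling="density",
    )
    bins = band_bins(f, band)
    if bins.size == 0:
        raise WindowRejected("band_unresolved", "no frequency bin in the band")
    df = f[1] - f[0]
    return float(np.sum(pxx[bins]) * df)


def brs_from_beats(
    beat_times, feature_values, rr_ms, cfg: SpectralConfig | None = None,
    input_feature: str = "SBP", modality: str = "ABP",
    t_start: float | None = None, t_end: float | None = None,
) -> tuple[BRSIndex, TransferEstimate]:
    """Convenience path: beat series → uniform series → BRS index.

    Input and output series are resampled on the *common* time span so the
    Welch segments align sample for sample.
    """
    cfg = cfg or SpectralConfig()
    t = np.asarray(beat_times, dtype=float)
    x_raw = np.asarray(feature_values, dtype=float)
    y_raw = np.asarray(rr_ms, dtype=float)
    ok = np.isfinite(x_raw) & np.isfinite(y_raw)
    gx, x = to_uniform_series(t[ok], x_raw[ok], cfg, t_start=t_start, t_end=t_end)
    gy, y = to_uniform_series(t[ok], y_raw[ok], cfg, t_start=t_start, t_end=t_end)
    est = estimate_transfer(x, y, cfg)
    idx = brs_index(est, cfg, input_feature=input_feature, modality=modality,
                    window=(float(gx[0]), float(gx[-1])))
    return idx, est
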