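"""Interventional comparison statistics and the 24-hour ambulatory profile.

Interventional arm: per participant × session × intervention, a BRS index
is computed for each (feature, modality) pair; the per-participant value is
the median over the repeated sessions; precision and correlation statistics
summarise the cohort. Ambulatory arm: BRS over 4-minute sliding windows
(75% overlap), medians of coherence-qualified windows over 1-hour spans
placed on a 15-minute grid, alongside HRV band powers, heart rate, and
reference cuff pressure readings.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError, WindowRejected
from .signal_io import EventList
from .spectral import SpectralConfig, brs_from_beats, hrv_band_power, to_uniform_series


# ---------------------------------------------------------------------------
# precision / correlation statistics


def intra_precision(values_by_participant: dict) -> float:
    """Within-participant precision as a percent of the grand mean.

    Pooled errors are each repeat's difference from its participant's
    median; the statistic is their sample SD (n−1) divided by the mean of
    the per-participant median indices, ×100.
    """
    errors, medians = [], []
    for vals in values_by_participant.values():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        med = np.median(v)
        medians.append(med)
        if v.size >= 2:
            errors.extend(v - med)
    if len(errors) < 2:
        raise ValidationError("need >= 2 repeats for >= 1 participant")
    grand = float(np.mean(medians))
    if grand == 0:
        raise ValidationError("grand mean BRS is zero; precision undefined")
    return float(np.std(errors, ddof=1) / grand * 100.0)


def inter_variation(medians_by_participant) -> float:
    """Between-participant variation: sample SD of the per-participant
    medians as a percent of their mean."""
    m = np.asarray(
        list(medians_by_participant.values())
        if isinstance(medians_by_participant, dict)
        else medians_by_participant,
        dtype=float,
    )
    m = m[np.isfinite(m)]
    if m.size < 2:
        raise ValidationError("need >= 2 participants")
    grand = float(np.mean(m))
    if grand == 0:
        raise ValidationError("grand mean BRS is zero; variation undefined")
    return float(np.std(m, ddof=1) / grand * 100.0)


def correlate_indices(a, b):
    """Pearson and Spearman correlation with two-sided p values.

    Missing pairs are dropped pairwise; zero variance in either series
    yields NaN correlations (flagged rather than raised).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValidationError("need >= 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return {"pearson_r": np.nan, "pearson_p": np.nan,
                "spearman_rho": np.nan, "spearman_p": np.nan, "n": int(a.size),
                "degenerate": True}
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    return {"pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "n": int(a.size), "degenerate": False}


# ---------------------------------------------------------------------------
# interventional study


@dataclass
class StudyResult:
    """Cohort table plus precision and correlation summaries.

    ``table`` holds one BRS per participant × intervention × index (median
    over sessions); ``per_trial`` keeps the session-level values;
    ``precision`` has intra-/inter-participant percentages per index;
    ``correlations`` the pairwise index correlations per intervention.
    """

    table: pd.DataFrame
    per_trial: pd.DataFrame
    precision: pd.DataFrame
    correlations: pd.DataFrame


def run_interventional(
    trial_tables,
    feature_columns: dict,
    cfg: SpectralConfig | None = None,
    average: str = "median",
) -> StudyResult:
    """Compute the full interventional comparison.

    Parameters
    ----------
    trial_tables : iterable of (participant, session, intervention, beats)
        ``beats`` is a DataFrame with column ``t`` (s), ``RR`` (ms) and the
        feature columns named in ``feature_columns``.
    feature_columns : dict
        index name → beat-table column, e.g. ``{"BRS_SBP_ABP": "SBP_ABP"}``.
    average : {"median", "mean"}
        Session aggregation; the median is the default outlier guard.
    """
    cfg = cfg or SpectralConfig()
    rows = []
    for participant, session, intervention, beats in trial_tables:
        for index_name, col in feature_columns.items():
            try:
                idx, _ = brs_from_beats(
                    beats["t"].to_numpy(), beats[col].to_numpy(),
                    beats["RR"].to_numpy(), cfg, input_feature=col,
                )
                rows.append(dict(participant=participant, session=session,
                                 intervention=intervention, index=index_name,
                                 brs=idx.value, coherence=idx.mean_lf_coherence,
                                 qualified=idx.qualified))
            except WindowRejected as exc:
                warnings.warn(
                    f"trial p{participant}/s{session}/{intervention}/{index_name} "
                    f"rejected: {exc}", stacklevel=2)
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        raise ValidationError("no trial produced a BRS estimate")

    agg = "median" if average == "median" else "mean"
    table = (
        per_trial.groupby(["participant", "intervention", "index"], as_index=False)
        .agg(brs=("brs", agg), coherence=("coherence", "median"),
             n_sessions=("brs", "size"))
    )
    short = per_trial.groupby(["participant", "intervention", "index"])["brs"].size()
    if (short < 3).any():
        warnings.warn("some participant/intervention cells have < 3 repeats; "
                      "median taken over available repeats", stacklevel=2)

    prec_rows = []
    for (intervention, index_name), grp in per_trial.groupby(["intervention", "index"]):
        by_p = {p: g["brs"].to_numpy() for p, g in grp.groupby("participant")}
        med_by_p = {p: float(np.median(v)) for p, v in by_p.items()}
        prec_rows.append(dict(
            intervention=intervention, index=index_name,
            intra_precision_pct=intra_precision(by_p),
            inter_variation_pct=inter_variation(med_by_p),
            mean_brs=float(np.mean(list(med_by_p.values()))),
        ))
    precision = pd.DataFrame(prec_rows)

    corr_rows = []
    for intervention, grp in table.groupby("intervention"):
        wide = grp.pivot(index="participant", columns="index", values="brs")
        names = list(wide.columns)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                c = correlate_indices(wide[a], wide[b])
                corr_rows.append(dict(intervention=intervention, index_a=a,
                                      index_b=b, **c))
    correlations = pd.DataFrame(corr_rows)
    return StudyResult(table=table, per_trial=per_trial,
                       precision=precision, correlations=correlations)


# ---------------------------------------------------------------------------
# ambulatory 24-h profile


@dataclass
class AmbulatoryConfig:
    window_s: float = 240.0        # 4-min BRS windows
    window_hop_s: float = 60.0     # 75% overlap
    span_s: float = 3600.0         # 1-h aggregation spans
    grid_s: float = 900.0          # 15-min display grid
    min_window_beats: int = 60     # fewer usable beats than this rejects a window
    min_coverage_frac: float = 0.75  # usable beats must span this much of the window


@dataclass
class AmbulatoryProfile:
    """15-minute-grid profile of BRS, HRV, HR and reference cuff pressure.

    ``grid`` columns (per feature F): ``BRS_F`` (median of qualified 4-min
    windows in the surrounding hour), ``BRS_F_se`` (standard error over the
    same windows), ``coh_F`` (their median coherence), ``qualified_pct_F``;
    plus ``HRV_LF``, ``HRV_HF`` (ms²), ``HR`` (bpm) and ``cuff_SBP``.
    ``windows`` keeps every 4-min window estimate with its rejection reason.
    """

    grid: pd.DataFrame
    windows: pd.DataFrame
    config: AmbulatoryConfig = field(default_factory=AmbulatoryConfig)


def ambulatory_windows(
    beats: pd.DataFrame,
    feature_columns: dict,
    scfg: SpectralConfig | None = None,
    acfg: AmbulatoryConfig | None = None,
) -> pd.DataFrame:
    """BRS, coherence, HRV and HR for every 4-minute sliding window.

    ``beats`` needs columns ``t`` (s), ``RR`` (ms) and the feature columns;
    disqualified beats should already hold NaN. Windows start on whole
    hops from the record start. Each row records the window start, the
    per-feature gain and coherence (NaN with a reason when rejected), the
    HRV band powers and the mean heart rate.
    """
    scfg = scfg or SpectralConfig()
    acfg = acfg or AmbulatoryConfig()
    t = beats["t"].to_numpy(dtype=float)
    rr = beats["RR"].to_numpy(dtype=float)
    # nominal record end on the hop grid, so a 24-h record at a 1-min hop
    # yields the full (1440 - 4) + 1 = 1437 windows
    t_end = float(np.ceil(t[-1] / acfg.window_hop_s) * acfg.window_hop_s)
    starts = np.arange(0.0, t_end - acfg.window_s + 1e-9, acfg.window_hop_s)
    rows = []
    for w0 in starts:
        w1 = w0 + acfg.window_s
        sel = (t >= w0) & (t < w1)
        row: dict = {"start": w0, "end": w1, "n_beats": int(np.count_nonzero(sel))}
        tw, rrw = t[sel], rr[sel]
        usable = np.isfinite(rrw)
        if np.count_nonzero(usable) < acfg.min_window_beats:
            row["reject"] = "too_few_beats"
            rows.append(row)
            continue
        tu = tw[usable]
        if tu[-1] - tu[0] < acfg.min_coverage_frac * acfg.window_s:
            row["reject"] = "coverage"
            rows.append(row)
            continue
        try:
            _, rr_u = to_uniform_series(tw[usable], rrw[usable], scfg,
                                        t_start=w0, t_end=w1)
            row["HRV_LF"] = hrv_band_power(rr_u, scfg.lf_band, scfg)
            row["HRV_HF"] = hrv_band_power(rr_u, scfg.hf_band, scfg)
            row["HR"] = float(60000.0 / np.nanmean(rrw))
        except WindowRejected as exc:
            row["reject"] = exc.reason
            rows.append(row)
            continue
        for name, col in feature_columns.items():
            x = beats[col].to_numpy(dtype=float)[sel]
            good = np.isfinite(x) & usable
            if (np.count_nonzero(good) < acfg.min_window_beats
                    or tw[good][-1] - tw[good][0] < acfg.min_coverage_frac * acfg.window_s):
                row[f"reject_{name}"] = "coverage"
                continue
            try:
                idx, _ = brs_from_beats(tw, x, rrw, scfg, input_feature=col,
                                        t_start=w0, t_end=w1)
                row[f"BRS_{name}"] = idx.value
                row[f"coh_{name}"] = idx.mean_lf_coherence
                row[f"qualified_{name}"] = idx.qualified
            except WindowRejected as exc:
                row[f"reject_{name}"] = exc.reason
        rows.append(row)
    return pd.DataFrame(rows)


def run_ambulatory(
    beats: pd.DataFrame,
    feature_columns: dict,
    events: EventList | None = None,
    cuff_readings: pd.DataFrame | None = None,
    scfg: SpectralConfig | None = None,
    acfg: AmbulatoryConfig | None = None,
) -> AmbulatoryProfile:
    """Full ambulatory profile from a qualified beat table (>= 2 h).

    1-hour spans are centred on 15-minute grid points; within a span the
    profile value is the median over the 4-minute windows whose mean LF
    coherence reaches the threshold, with the standard error taken over
    those same qualified windows. Cuff readings, when given as a
    ``(t, SBP)`` table, are averaged per span as reference context only —
    no BRS is derived from them.
    """
    scfg = scfg or SpectralConfig()
    acfg = acfg or AmbulatoryConfig()
    t = beats["t"].to_numpy(dtype=float)
    if t[-1] - t[0] < 2 * acfg.span_s:
        raise ValidationError("ambulatory profile needs >= 2 h of beats")
    win = ambulatory_windows(beats, feature_columns, scfg, acfg)

    half = acfg.span_s / 2.0
    t_end = float(np.ceil(t[-1] / acfg.grid_s) * acfg.grid_s)
    grid_pts = np.arange(half, t_end - half + 1e-9, acfg.grid_s)
    rows = []
    for g in grid_pts:
        lo, hi = g - half, g + half
        inside = win[(win["start"] >= lo) & (win["end"] <= hi)]
        row: dict = {"t": g}
        for name in feature_columns:
            bcol, ccol, qcol = f"BRS_{name}", f"coh_{name}", f"qualified_{name}"
            have = inside.dropna(subset=[bcol]) if bcol in inside else inside.iloc[0:0]
            total = len(inside)
            if len(have) and qcol in have:
                q = have[have[qcol].astype(bool)]
            else:
                q = have.iloc[0:0]
            row[f"qualified_pct_{name}"] = 100.0 * len(q) / total if total else np.nan
            if len(q):
                row[f"BRS_{name}"] = float(q[bcol].median())
                row[f"BRS_{name}_se"] = (
                    float(q[bcol].std(ddof=1) / np.sqrt(len(q))) if len(q) > 1 else 0.0
                )
                row[f"coh_{name}"] = float(q[ccol].median())
            else:
                row[f"BRS_{name}"] = np.nan
                row[f"BRS_{name}_se"] = np.nan
                row[f"coh_{name}"] = np.nan
        for col in ("HRV_LF", "HRV_HF", "HR"):
            row[col] = float(inside[col].mean()) if col in inside else np.nan
        if cuff_readings is not None and len(cuff_readings):
            ct = cuff_readings["t"].to_numpy(dtype=float)
            m = (ct >= lo) & (ct <= hi)
            row["cuff_SBP"] = float(cuff_readings["SBP"].to_numpy()[m].mean()) if m.any() else np.nan
        rows.append(row)
    return AmbulatoryProfile(grid=pd.DataFrame(rows), windows=win, config=acfg)
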