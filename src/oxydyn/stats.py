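"""Agreement statistics: Pearson r, Bland-Altman, bias t-test, error histograms.

The sign convention throughout is bias = mean(measured − predicted): a
positive bias means the predictor under-estimates.  Limits of agreement are
bias ± 1.96·SD of the differences (sample SD, n−1 denominator); the same
1.96·SD half-width doubles as the confidence interval around the bias in
Bland-Altman reporting.  Correlation p-values treat 1-Hz samples as
independent, which overstates significance for autocorrelated series — they
are reported for completeness, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import participant_mng
from .mets import intensity_profile
from .preprocess import SensorFrame


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AgreementReport:
    """Pearson correlation plus Bland-Altman bias / limits for one comparison."""

    r: float
    p_r: float
    bias: float
    loa_low: float
    loa_high: float
    ci95_halfwidth: float
    t_bias: float
    p_bias: float
    n: int
    degenerate: bool = False  # identical series: t-test undefined


def pearson_r(a, b) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value from the t transform."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise StatsError("pearson_r needs two equal-length series of length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise StatsError("pearson_r undefined for a zero-variance series")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def bland_altman(measured, predicted) -> AgreementReport:
    """Bland-Altman agreement of predicted against measured values.

    Differences d = measured − predicted; bias = mean(d); limits of agreement
    bias ± 1.96·SD(d); one-sample t-test of d against zero.  Identical series
    yield zero bias/limits with the t-test flagged degenerate.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size < 3:
        raise StatsError("bland_altman needs two equal-length series of length >= 3")
    d = m - p
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        t_bias, p_bias = np.nan, np.nan
    else:
        t_res = sps.ttest_1samp(d, 0.0)
        t_bias, p_bias = float(t_res.statistic), float(t_res.pvalue)
    try:
        r, p_r = pearson_r(m, p)
    except StatsError:
        r, p_r = np.nan, np.nan
    half = 1.96 * sd
    return AgreementReport(
        r=r,
        p_r=p_r,
        bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        ci95_halfwidth=half,
        t_bias=t_bias,
        p_bias=p_bias,
        n=int(m.size),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ErrorHistogram:
    bin_edges: np.ndarray
    relative_frequencies: np.ndarray


def error_distribution(measured, predicted, n_bins: int = 20) -> ErrorHistogram:
    """Relative-frequency histogram of the prediction error (measured − predicted)."""
    if n_bins < 1:
        raise StatsError("n_bins must be >= 1")
    d = np.asarray(measured, dtype=float) - np.asarray(predicted, dtype=float)
    counts, edges = np.histogram(d, bins=n_bins)
    return ErrorHistogram(bin_edges=edges, relative_frequencies=counts / counts.sum())


@dataclass
class StudyReport:
    """Cohort-level validation bundle mirroring the study's result structure."""

    adl_pooled: AgreementReport
    prts_pooled: AgreementReport
    adl_per_participant: pd.DataFrame
    prts_per_participant: pd.DataFrame
    mng_table: pd.DataFrame
    mng_agreement: AgreementReport
    mets_table: pd.DataFrame
    extras: dict = field(default_factory=dict)


def study_report(
    frames: list[SensorFrame],
    predictions: dict[str, np.ndarray],
    schedule,
    f_max: float = 0.008,
    include_first: bool = True,
) -> StudyReport:
    """Full validation report for a predicted cohort.

    ``predictions`` maps participant id to a full-frame 1-Hz prediction
    aligned with that participant's SensorFrame.  The reference is always the
    raw (unfiltered) measured oxygen uptake.  Pooled statistics concatenate
    all participants' samples; per-participant tables support the
    mean ± SD view of individual analyses.
    """
    required = {"ADL", "PRTS1", "PRTS2"}
    for frame in frames:
        have = {s.label for s in frame.segments}
        if not required <= have:
            raise StatsError(
                f"participant {frame.participant_id}: missing segments {sorted(required - have)}"
            )

    per_adl, per_prts, mng_rows = [], [], []
    adl_m, adl_p, prts_m, prts_p = [], [], [], []
    mets_m_all, mets_p_all = [], []
    for frame in frames:
        pred = np.asarray(predictions[frame.participant_id], dtype=float)
        vo2 = np.asarray(frame.channels["VO2"], dtype=float)
        mask_adl = frame.segment_mask("ADL")
        mask_prts = frame.segment_mask("PRTS1", "PRTS2")
        for mask, pool_m, pool_p, rows in (
            (mask_adl, adl_m, adl_p, per_adl),
            (mask_prts, prts_m, prts_p, per_prts),
        ):
            rep = bland_altman(vo2[mask], pred[mask])
            rows.append({"participant_id": frame.participant_id, "r": rep.r,
                         "bias": rep.bias, "n": rep.n})
            pool_m.append(vo2[mask])
            pool_p.append(pred[mask])
        mng_meas, mng_pred = participant_mng(
            frame, pred, schedule, f_max=f_max, include_first=include_first
        )
        mng_rows.append(
            {
                "participant_id": frame.participant_id,
                "mng_measured_pct": mng_meas.mng,
                "mng_predicted_pct": mng_pred.mng,
                "harmonics": ",".join(map(str, mng_meas.harmonics_used)),
                "include_first": include_first,
            }
        )
        mets_m_all.append(vo2[mask_adl])
        mets_p_all.append(pred[mask_adl])

    mng_df = pd.DataFrame(mng_rows)
    if len(mng_df) >= 3:
        mng_agreement = bland_altman(
            mng_df["mng_measured_pct"].to_numpy(), mng_df["mng_predicted_pct"].to_numpy()
        )
    else:  # too few participants for cohort-level agreement: report bias only
        d = (mng_df["mng_measured_pct"] - mng_df["mng_predicted_pct"]).to_numpy()
        mng_agreement = AgreementReport(
            r=np.nan, p_r=np.nan, bias=float(d.mean()), loa_low=np.nan, loa_high=np.nan,
            ci95_halfwidth=np.nan, t_bias=np.nan, p_bias=np.nan, n=len(d), degenerate=True,
        )
    mets = intensity_profile(np.concatenate(mets_m_all), np.concatenate(mets_p_all))
    return StudyReport(
        adl_pooled=bland_altman(np.concatenate(adl_m), np.concatenate(adl_p)),
        prts_pooled=bland_altman(np.concatenate(prts_m), np.concatenate(prts_p)),
        adl_per_participant=pd.DataFrame(per_adl),
        prts_per_participant=pd.DataFrame(per_prts),
        mng_table=mng_df,
        mng_agreement=mng_agreement,
        mets_table=mets.cluster_means,
        extras={"mets_excluded_fraction": mets.excluded_fraction},
    )
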