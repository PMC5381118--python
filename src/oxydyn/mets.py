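"""Metabolic-equivalent (METS) conversion, resting metabolic rate, intensity bands.

One MET is the conventional 3.5 ml·min⁻¹·kg⁻¹ of oxygen uptake.  Samples are
banded into rest (< 2 METS), light [2, 4), moderate [4, 6) and excluded
(≥ 6 METS — vigorous activity outside the protocol's scope); the half-open
edges make the 3.9 → light / 4.0 → moderate assignments deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Segment

#: ml·min⁻¹·kg⁻¹ of oxygen uptake per metabolic equivalent.
ML_PER_MET = 3.5

#: Band edges (lower-inclusive) for rest / light / moderate / excluded.
BAND_EDGES = (2.0, 4.0, 6.0)

LABELS = ("rest", "light", "moderate", "excluded")


class MetsError(ValueError):
    pass


def vo2_to_mets(vo2, ml_per_met: float = ML_PER_MET):
    """Convert oxygen uptake (ml·min⁻¹·kg⁻¹) to metabolic equivalents."""
    vo2 = np.asarray(vo2, dtype=float)
    if (vo2 < 0).any():
        raise MetsError("oxygen uptake must be non-negative")
    return vo2 / ml_per_met


def resting_metabolic_rate(
    vo2_series: np.ndarray,
    time: np.ndarray,
    rest_segment: Segment,
    window_s: int = 60,
) -> float:
    """Resting metabolic rate: mean of a 60-s window of resting oxygen uptake.

    The window is placed at the end of the rest segment (the most settled
    portion).  Raises when the segment is shorter than the window.
    """
    time = np.asarray(time)
    mask = (time >= rest_segment.start) & (time < rest_segment.end)
    values = np.asarray(vo2_series, dtype=float)[mask]
    if values.size < window_s:
        raise MetsError(
            f"rest segment has {values.size} s, need at least {window_s} s"
        )
    return float(values[-window_s:].mean())


def cluster_intensity(mets_series) -> np.ndarray:
    """Band labels per sample: rest < 2, light [2,4), moderate [4,6), excluded >= 6."""
    mets = np.asarray(mets_series, dtype=float)
    if not np.isfinite(mets).all():
        raise MetsError("METS values must be finite")
    lo, mid, hi = BAND_EDGES
    labels = np.empty(mets.shape, dtype=object)
    labels[mets < lo] = "rest"
    labels[(mets >= lo) & (mets < mid)] = "light"
    labels[(mets >= mid) & (mets < hi)] = "moderate"
    labels[mets >= hi] = "excluded"
    return labels


@dataclass
class IntensityProfile:
    """Per-sample METS, band labels and the per-band measured/predicted means."""

    mets_measured: np.ndarray
    mets_predicted: np.ndarray
    labels: np.ndarray
    rmr_vo2: float | None
    cluster_means: pd.DataFrame
    excluded_fraction: float


def intensity_profile(
    vo2_measured: np.ndarray,
    vo2_predicted: np.ndarray,
    time: np.ndarray | None = None,
    rest_segment: Segment | None = None,
    ml_per_met: float = ML_PER_MET,
) -> IntensityProfile:
    """Cluster samples by measured METS and compare measured vs predicted means.

    Banding always follows the *measured* intensity, so the predicted means
    per band quantify how well the predictor separates metabolic demands.
    """
    mets_m = vo2_to_mets(vo2_measured, ml_per_met)
    mets_p = vo2_to_mets(np.clip(vo2_predicted, 0.0, None), ml_per_met)
    labels = cluster_intensity(mets_m)
    rows = []
    for lab in LABELS:
        mask = labels == lab
        rows.append(
            {
                "cluster": lab,
                "n_samples": int(mask.sum()),
                "mets_measured_mean": float(mets_m[mask].mean()) if mask.any() else np.nan,
                "mets_predicted_mean": float(mets_p[mask].mean()) if mask.any() else np.nan,
            }
        )
    rmr = None
    if rest_segment is not None and time is not None:
        rmr = resting_metabolic_rate(np.asarray(vo2_measured), time, rest_segment)
    return IntensityProfile(
        mets_measured=mets_m,
        mets_predicted=mets_p,
        labels=labels,
        rmr_vo2=rmr,
        cluster_means=pd.DataFrame(rows),
        excluded_fraction=float((labels == "excluded").mean()),
    )
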