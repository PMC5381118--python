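"""Aerobic system identification in the frequency domain.

Hip acceleration is the system input and oxygen uptake (measured or
predicted) the output.  The two PRTS repeats are time-aligned and averaged,
both series are Fourier-transformed over exactly one protocol period (so the
stimulated harmonics fall exactly on DFT bins and there is no leakage), and
the per-harmonic amplitude gains |Y_k|/|X_k| are normalised by the gain at
the first harmonic.  The mean of the normalised gains (MNG, in percent) is
the scalar index of aerobic temporal dynamics: normalisation removes the
static gain, so a faster system — flatter gain roll-off — scores higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SensorFrame
from .prts import HarmonicSet, PRTSSchedule, stimulated_harmonics


class DynamicsError(ValueError):
    pass


@dataclass(frozen=True)
class GainSpectrum:
    """Per-harmonic input/output amplitudes, gains and first-harmonic-normalised gains."""

    harmonic_indices: tuple[int, ...]
    frequencies: tuple[float, ...]
    input_amplitude: np.ndarray
    output_amplitude: np.ndarray
    gain: np.ndarray
    normalized_gain: np.ndarray


@dataclass(frozen=True)
class MNGResult:
    """Mean normalised gain in percent, with the conventions that produced it."""

    mng: float
    harmonics_used: tuple[int, ...]
    include_first: bool
    input_channel: str = "Hacc"


def average_prts_repeats(series_1: np.ndarray, series_2: np.ndarray) -> np.ndarray:
    """Point-wise mean of two protocol-aligned single-period responses."""
    a = np.asarray(series_1, dtype=float)
    b = np.asarray(series_2, dtype=float)
    if a.shape != b.shape:
        raise DynamicsError(f"repeat length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


def gain_spectrum(
    input_series: np.ndarray,
    output_series: np.ndarray,
    harmonics: HarmonicSet,
) -> GainSpectrum:
    """Amplitude gains at the stimulated harmonics of one protocol period.

    Both series must be exactly one period long at 1 Hz so harmonic k sits on
    DFT bin k.  The mean is removed and no window applied — the stimulus is
    periodic, bins are exact, and a window would only bias the amplitudes.
    Raises when a requested harmonic carries no input stimulus (which is how
    even harmonics of the antiperiodic PRTS present).
    """
    x = np.asarray(input_series, dtype=float)
    y = np.asarray(output_series, dtype=float)
    if x.shape != y.shape:
        raise DynamicsError("input and output series must have equal length")
    n = x.size
    expected_n = int(round(1.0 / harmonics.fundamental))
    if n != expected_n:
        raise DynamicsError(
            f"series length {n} does not match the harmonic fundamental "
            f"(expected one period = {expected_n} samples at 1 Hz)"
        )
    X = np.fft.rfft(x - x.mean())
    Y = np.fft.rfft(y - y.mean())
    amp_x_full = np.abs(X) * 2.0 / n
    amp_y_full = np.abs(Y) * 2.0 / n
    ks = np.asarray(harmonics.indices, dtype=int)
    floor = 1e-12 * amp_x_full.max()
    for k in ks:
        if amp_x_full[k] < floor:
            raise DynamicsError(f"no stimulus at harmonic {int(k)}")
    amp_x = amp_x_full[ks]
    amp_y = amp_y_full[ks]
    gain = amp_y / amp_x
    return GainSpectrum(
        harmonic_indices=tuple(int(k) for k in ks),
        frequencies=tuple(harmonics.frequencies),
        input_amplitude=amp_x,
        output_amplitude=amp_y,
        gain=gain,
        normalized_gain=gain / gain[0],
    )


def mean_normalized_gain(
    spectrum: GainSpectrum, include_first: bool = True, input_channel: str = "Hacc"
) -> MNGResult:
    """MNG = 100 × mean of the normalised gains over the harmonics used.

    The first harmonic's normalised gain is identically 1; by default it
    participates in the mean (``include_first=True``), the alternative
    convention is exposed because either reading of "mean of the normalised
    gains" is defensible.
    """
    gains = spectrum.normalized_gain
    ks = spectrum.harmonic_indices
    if not include_first:
        keep = [i for i, k in enumerate(ks) if k != 1]
        gains = gains[keep]
        ks = tuple(ks[i] for i in keep)
    if len(ks) == 0:
        raise DynamicsError("no harmonics left to average")
    return MNGResult(
        mng=float(100.0 * gains.mean()),
        harmonics_used=ks,
        include_first=include_first,
        input_channel=input_channel,
    )


def first_order_mng_closed_form(
    tau: float, harmonics: HarmonicSet, include_first: bool = True
) -> float:
    """Analytic MNG (percent) of a linear first-order system with time constant tau.

    |H(f)| = 1/sqrt(1 + (2*pi*f*tau)^2), so the normalised gain at harmonic k is
    sqrt((1 + (2*pi*f1*tau)^2) / (1 + (2*pi*f_k*tau)^2)).  Serves as the
    independent oracle for the simulation/analysis round trip: tau = 0 gives
    100 %, and for harmonics {1,3,5} the tau -> inf limit is the mean of
    (1, 1/3, 1/5) = 51.11 %.
    """
    if tau < 0:
        raise DynamicsError("tau must be non-negative")
    f1 = harmonics.fundamental
    ks = [k for k in harmonics.indices if include_first or k != 1]
    if not ks:
        raise DynamicsError("no harmonics to average")
    num = 1.0 + (2.0 * np.pi * f1 * tau) ** 2
    gains = [np.sqrt(num / (1.0 + (2.0 * np.pi * k * f1 * tau) ** 2)) for k in ks]
    return float(100.0 * np.mean(gains))


def participant_mng(
    frame: SensorFrame,
    predictions: np.ndarray,
    schedule: PRTSSchedule,
    f_max: float = 0.008,
    include_first: bool = True,
) -> tuple[MNGResult, MNGResult]:
    """Measured-based and predicted-based MNG for one participant.

    Hip-acceleration input and both oxygen-uptake outputs are cut to the
    PRTS1/PRTS2 segments (one period each), repeat-averaged, and fed through
    the same input spectrum.  ``predictions`` must align sample-for-sample
    with ``frame.time``.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape[0] != frame.n_samples:
        raise DynamicsError("predictions must align with the sensor frame")
    harmonics = stimulated_harmonics(schedule, f_max=f_max)
    n_period = int(round(schedule.period))

    labels = {s.label for s in frame.segments}
    missing = {"PRTS1", "PRTS2"} - labels
    if missing:
        raise DynamicsError(f"missing PRTS segments: {sorted(missing)}")

    def cut(values: np.ndarray, label: str) -> np.ndarray:
        seg = next(s for s in frame.segments if s.label == label)
        mask = (frame.time >= seg.start) & (frame.time < seg.end)
        out = np.asarray(values)[mask]
        if out.size != n_period:
            raise DynamicsError(
                f"segment {label} has {out.size} samples, expected one period ({n_period})"
            )
        return out

    hacc = average_prts_repeats(
        cut(frame.channels["Hacc"], "PRTS1"), cut(frame.channels["Hacc"], "PRTS2")
    )
    vo2_meas = average_prts_repeats(
        cut(frame.channels["VO2"], "PRTS1"), cut(frame.channels["VO2"], "PRTS2")
    )
    vo2_pred = average_prts_repeats(cut(predictions, "PRTS1"), cut(predictions, "PRTS2"))

    spec_meas = gain_spectrum(hacc, vo2_meas, harmonics)
    spec_pred = gain_spectrum(hacc, vo2_pred, harmonics)
    return (
        mean_normalized_gain(spec_meas, include_first=include_first),
        mean_normalized_gain(spec_pred, include_first=include_first),
    )
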