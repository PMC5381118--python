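"""Synthetic participants with known first-order cardiorespiratory kinetics.

Each participant walks the full study protocol — rest, a warm-up plus one
PRTS period, a block of simulated activities of daily living, then a second
warm-up plus PRTS period — and their oxygen uptake and heart rate respond to
cadence through first-order dynamics with participant-specific time
constants.  Ventilation and breathing frequency are coupled to the
noise-free oxygen uptake, hip acceleration tracks cadence, and oxygen uptake
is re-sampled at irregular breath events before Gaussian measurement noise
is added, so generated recordings exercise the same preprocessing path as
real ones.  Every participant stores their generative truth (parameters,
noise-free channels, closed-form MNG) for recovery tests.

The discretisation is the exact exponential-hold update
``v[t] = target[t-1] + (v[t-1] - target[t-1]) * exp(-1/tau)`` with the
cadence drive held constant over each 1-s step, so sampled trajectories are
exact solutions of the continuous first-order system, not Euler
approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dynamics import first_order_mng_closed_form
from .preprocess import RawChannel, Segment, SensorFrame, synchronize_resample
from .prts import PRTSSchedule, cadence_signal, default_schedule, stimulated_harmonics

#: Default activities-of-daily-living script: (label, duration s, cadence steps·min⁻¹).
#: Sitting and computer work are resting; shelf organisation and carrying are
#: light; stair climbing and self-paced walking are moderate intensity.
DEFAULT_ADL_SCRIPT: tuple[tuple[str, int, float], ...] = (
    ("sit", 240, 0.0),
    ("shelf", 180, 55.0),
    ("carry", 150, 65.0),
    ("stairs", 120, 100.0),
    ("walk", 210, 105.0),
    ("computer", 240, 0.0),
)

DEFAULT_NOISE_SD = {
    "VO2": 0.5,   # ml·min⁻¹·kg⁻¹, breath-by-breath scatter
    "HR": 2.0,    # bpm
    "VE": 1.5,    # L·min⁻¹
    "BF": 1.5,    # breaths·min⁻¹
    "Hacc": 0.05, # g
    "CAD": 2.0,   # steps·min⁻¹
}


class CohortError(ValueError):
    pass


@dataclass
class SimParams:
    """Generative parameters for one synthetic participant."""

    tau_vo2: float = 30.0          # s, oxygen-uptake time constant
    static_gain: float = 0.105     # ml·min⁻¹·kg⁻¹ per steps·min⁻¹
    delay: float = 0.0             # s, pure transport delay of the cadence drive
    vo2_rest: float = 3.7          # ml·min⁻¹·kg⁻¹
    tau_hr: float = 22.0           # s, heart-rate time constant
    hr_rest: float = 65.0          # bpm
    hr_gain: float = 0.47          # bpm per steps·min⁻¹
    ve_per_vo2: float = 2.3        # L·min⁻¹ per ml·min⁻¹·kg⁻¹
    bf_base: float = 12.0          # breaths·min⁻¹ at rest
    bf_gain: float = 0.8           # breaths·min⁻¹ per ml·min⁻¹·kg⁻¹ above rest
    hacc_base: float = 0.05        # g at rest
    hacc_per_cadence: float = 0.009  # g per steps·min⁻¹
    breath_interval_mean: float = 3.0  # s, mean of exponential inter-breath times
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_vo2 < 0 or self.tau_hr < 0:
            raise CohortError("time constants must be non-negative")
        if self.vo2_rest <= 0:
            raise CohortError("resting oxygen uptake must be positive")
        if any(v < 0 for v in self.noise_sd.values()):
            raise CohortError("noise SDs must be non-negative")


@dataclass
class SimTruth:
    """Ground truth stored with each generated participant."""

    params: SimParams
    clean: dict[str, np.ndarray]
    true_mng: float


def first_order_response(drive: np.ndarray, tau: float, initial: float) -> np.ndarray:
    """Exact sampled response of dv/dt = (drive - v)/tau with 1-s zero-order hold."""
    drive = np.asarray(drive, dtype=float)
    if tau == 0:
        return drive.copy()
    a = np.exp(-1.0 / tau)
    out = np.empty_like(drive)
    out[0] = initial
    for t in range(1, len(drive)):
        out[t] = drive[t - 1] + (out[t - 1] - drive[t - 1]) * a
    return out


def _protocol_timeline(
    schedule: PRTSSchedule,
    adl_script=DEFAULT_ADL_SCRIPT,
    rest_duration: int = 180,
) -> tuple[np.ndarray, list[Segment]]:
    """Concatenate rest, warm-up + PRTS, ADL, warm-up + PRTS into one cadence series."""
    prts = cadence_signal(schedule, include_warmup=True)  # warm-up + one period
    warm_n = int(round(schedule.warmup_duration))
    period_n = int(round(schedule.period))
    adl = np.concatenate(
        [np.full(int(dur), cad, dtype=float) for _, dur, cad in adl_script]
    )
    cad = np.concatenate([np.zeros(rest_duration), prts, adl, prts])
    t = rest_duration
    segments = [Segment("REST", 0, rest_duration)]
    segments.append(Segment("PRTS1", t + warm_n, t + warm_n + period_n))
    t += warm_n + period_n
    segments.append(Segment("ADL", t, t + len(adl)))
    t += len(adl)
    segments.append(Segment("PRTS2", t + warm_n, t + warm_n + period_n))
    return cad, segments


def simulate_participant(
    params: SimParams,
    schedule: PRTSSchedule | None = None,
    adl_script=DEFAULT_ADL_SCRIPT,
    rest_duration: int = 180,
    breath_sampling: bool = True,
    participant_id: str = "P00",
) -> tuple[SensorFrame, SimTruth]:
    """Generate one participant's full multichannel recording plus ground truth.

    Oxygen uptake and heart rate follow first-order kinetics driven by
    cadence; ventilation and breathing frequency couple instantaneously to
    the noise-free oxygen uptake; hip acceleration is piecewise-linear in
    cadence.  With ``breath_sampling`` the oxygen-uptake channel is sampled
    at exponential breath intervals then re-synchronised to 1 Hz through the
    standard preprocessing path.
    """
    if schedule is None:
        schedule = default_schedule()
    rng = np.random.default_rng(params.seed)
    cad, segments = _protocol_timeline(schedule, adl_script, rest_duration)
    n = len(cad)
    time = np.arange(n, dtype=float)

    d = int(round(params.delay))
    cad_delayed = np.concatenate([np.full(d, cad[0]), cad[: n - d]]) if d else cad

    vo2_drive = params.vo2_rest + params.static_gain * cad_delayed
    vo2_clean = first_order_response(vo2_drive, params.tau_vo2, vo2_drive[0])
    hr_drive = params.hr_rest + params.hr_gain * cad_delayed
    hr_clean = first_order_response(hr_drive, params.tau_hr, hr_drive[0])
    ve_clean = params.ve_per_vo2 * vo2_clean
    bf_clean = params.bf_base + params.bf_gain * (vo2_clean - params.vo2_rest)
    hacc_clean = params.hacc_base + params.hacc_per_cadence * cad

    sd = params.noise_sd
    channels = {
        "HR": RawChannel("HR", time, hr_clean + rng.normal(0, sd.get("HR", 0), n)),
        "VE": RawChannel("VE", time, np.clip(ve_clean + rng.normal(0, sd.get("VE", 0), n), 0, None)),
        "BF": RawChannel("BF", time, np.clip(bf_clean + rng.normal(0, sd.get("BF", 0), n), 0, None)),
        "Hacc": RawChannel("Hacc", time, np.clip(hacc_clean + rng.normal(0, sd.get("Hacc", 0), n), 0, None)),
        "CAD": RawChannel("CAD", time, np.clip(cad + rng.normal(0, sd.get("CAD", 0), n), 0, None)),
    }

    if breath_sampling:
        gaps = rng.exponential(params.breath_interval_mean, size=int(2 * n / max(params.breath_interval_mean, 0.5)) + 16)
        breath_t = np.concatenate([[0.0], np.cumsum(gaps)])
        breath_t = breath_t[breath_t < n - 1]
        breath_t = np.append(breath_t, n - 1.0)  # cover the full window, no extrapolation
        vo2_at_breaths = np.interp(breath_t, time, vo2_clean)
        vo2_noisy = np.clip(vo2_at_breaths + rng.normal(0, sd.get("VO2", 0), len(breath_t)), 0, None)
        channels["VO2"] = RawChannel("VO2", breath_t, vo2_noisy)
    else:
        channels["VO2"] = RawChannel(
            "VO2", time, np.clip(vo2_clean + rng.normal(0, sd.get("VO2", 0), n), 0, None)
        )

    frame = synchronize_resample(channels, segments, participant_id=participant_id)
    harmonics = stimulated_harmonics(schedule)
    truth = SimTruth(
        params=params,
        clean={
            "VO2": vo2_clean,
            "HR": hr_clean,
            "VE": ve_clean,
            "BF": bf_clean,
            "Hacc": hacc_clean,
            "CAD": cad,
        },
        true_mng=first_order_mng_closed_form(params.tau_vo2, harmonics),
    )
    return frame, truth


def draw_cohort_params(
    n: int,
    tau_range: tuple[float, float] = (20.0, 60.0),
    seed: int | None = None,
    noise_scale: float = 1.0,
) -> list[SimParams]:
    """Draw per-participant parameters from participant-indexed substreams.

    Physiological ranges: resting oxygen uptake 3.2–4.2 ml·min⁻¹·kg⁻¹,
    static gain 0.095–0.115 ml·min⁻¹·kg⁻¹ per steps·min⁻¹ (keeps PRTS peaks
    below 6 METS), heart-rate kinetics ~25 % faster than oxygen uptake.
    """
    if n < 2:
        raise CohortError("a cohort needs at least 2 participants")
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        tau = float(rng.uniform(*tau_range))
        noise = {k: v * noise_scale for k, v in DEFAULT_NOISE_SD.items()}
        out.append(
            SimParams(
                tau_vo2=tau,
                static_gain=float(rng.uniform(0.095, 0.115)),
                vo2_rest=float(rng.uniform(3.2, 4.2)),
                tau_hr=float(0.75 * tau * rng.uniform(0.9, 1.1)),
                hr_rest=float(rng.uniform(58, 72)),
                hr_gain=float(rng.uniform(0.42, 0.52)),
                ve_per_vo2=float(rng.uniform(2.1, 2.5)),
                bf_base=float(rng.uniform(11, 14)),
                bf_gain=float(rng.uniform(0.7, 0.9)),
                hacc_per_cadence=float(rng.uniform(0.0085, 0.0095)),
                noise_sd=noise,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return out


def simulate_cohort(
    n: int = 16,
    tau_range: tuple[float, float] = (20.0, 60.0),
    seed: int | None = None,
    schedule: PRTSSchedule | None = None,
    breath_sampling: bool = True,
    noise_scale: float = 1.0,
    adl_script=DEFAULT_ADL_SCRIPT,
) -> list[tuple[SensorFrame, SimTruth]]:
    """Generate a full synthetic cohort (default 16 participants).

    Identical protocol timing for everyone; disjoint noise substreams per
    participant; regeneration from the same seed is bit-identical.
    """
    params = draw_cohort_params(n, tau_range=tau_range, seed=seed, noise_scale=noise_scale)
    if schedule is None:
        schedule = default_schedule()
    cohort = []
    for i, p in enumerate(params):
        cohort.append(
            simulate_participant(
                p,
                schedule=schedule,
                adl_script=adl_script,
                breath_sampling=breath_sampling,
                participant_id=f"P{i:02d}",
            )
        )
    return cohort


def truth_summary(cohort: list[tuple[SensorFrame, SimTruth]]) -> dict:
    """JSON-ready ground-truth table for a generated cohort."""
    return {
        frame.participant_id: {
            "tau_vo2": truth.params.tau_vo2,
            "true_mng": truth.true_mng,
            "params": {
                k: v for k, v in asdict(truth.params).items() if not isinstance(v, dict)
            },
        }
        for frame, truth in cohort
    }
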