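"""Pseudorandom ternary sequence (PRTS) walking protocol.

A maximal-length ternary m-sequence from a GF(3) linear-feedback shift
register drives the walking cadence between three levels (default 75/105/135
steps·min⁻¹, 30 s per symbol).  With the antisymmetric symbol mapping
{0→0, 1→+1, 2→−1} the centred cadence signal is antiperiodic —
c(t + period/2) = −c(t) — so even harmonics of the protocol period carry no
stimulus at all and the system can only be identified at odd harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Feedback taps of primitive polynomials over GF(3), keyed by degree.
#: Taps a_1..a_m define the recurrence s[n] = (a_1 s[n-1] + ... + a_m s[n-m]) mod 3
#: for f(x) = x^m + c_{m-1} x^{m-1} + ... + c_0 via a_j = -c_{m-j} mod 3.
#: Degree 3 (x^3 + 2x + 1) gives the 26-symbol / 13-min protocol.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),          # x^2 + x + 2
    3: (0, 1, 2),       # x^3 + 2x + 1
    4: (0, 0, 2, 1),    # x^4 + x + 2
    5: (0, 0, 0, 1, 2), # x^5 + 2x + 1
}

#: Field-element to level mapping making the cadence signal antiperiodic.
SYMBOL_MAP = {0: 0, 1: +1, 2: -1}


class PRTSError(ValueError):
    """Raised for invalid generator or schedule parameters."""


def generate_ternary_msequence(
    degree: int = 3,
    taps: tuple[int, ...] | None = None,
    initial_state: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Generate one period of a maximal-length ternary m-sequence over {0, 1, 2}.

    The shift register iterates s[n] = sum_j taps[j] * s[n-1-j] mod 3.  The
    measured period is checked against 3^degree − 1; a shorter cycle means the
    feedback polynomial is not primitive and raises.
    """
    if taps is None:
        if degree not in PRIMITIVE_TAPS:
            raise PRTSError(f"no default feedback taps for degree {degree}")
        taps = PRIMITIVE_TAPS[degree]
    if len(taps) != degree:
        raise PRTSError(f"need {degree} feedback taps, got {len(taps)}")
    if initial_state is None:
        initial_state = tuple([0] * (degree - 1) + [1])
    if len(initial_state) != degree:
        raise PRTSError("initial state length must equal the generator degree")
    if all(s % 3 == 0 for s in initial_state):
        raise PRTSError("initial state must not be all zero")

    full_period = 3**degree - 1
    state = tuple(s % 3 for s in initial_state)
    start = state
    out: list[int] = []
    for n in range(full_period):
        new = sum(t * s for t, s in zip(taps, state)) % 3
        state = (new,) + state[:-1]
        out.append(new)
        if state == start and n + 1 < full_period:
            raise PRTSError(
                f"feedback taps {taps} are not primitive: period {n + 1} < {full_period}"
            )
    if state != start:
        raise PRTSError(f"feedback taps {taps} are not primitive (no return to start)")
    return np.array(out, dtype=int)


@dataclass(frozen=True)
class PRTSSchedule:
    """Cadence schedule: symbols over {−1, 0, +1}, 30-s steps, 75/105/135 levels."""

    symbols: np.ndarray
    step_duration: float = 30.0
    base_cadence: float = 105.0
    level_delta: float = 30.0
    warmup_duration: float = 300.0

    @property
    def n_symbols(self) -> int:
        return len(self.symbols)

    @property
    def period(self) -> float:
        """Protocol period in seconds (symbols × step duration)."""
        return self.n_symbols * self.step_duration

    @property
    def fundamental(self) -> float:
        """Fundamental frequency 1/period in Hz."""
        return 1.0 / self.period

    @property
    def cadence_levels(self) -> tuple[float, float, float]:
        b, d = self.base_cadence, self.level_delta
        return (b - d, b, b + d)


def build_prts_schedule(
    field_symbols: np.ndarray,
    step_duration: float = 30.0,
    base_cadence: float = 105.0,
    level_delta: float = 30.0,
    warmup_duration: float = 300.0,
) -> PRTSSchedule:
    """Map GF(3) symbols to {−1, 0, +1} levels and wrap them into a schedule.

    With the default 26-symbol degree-3 sequence this yields the 780-s
    (13-min) protocol preceded by a 300-s warm-up drawn from the sequence
    tail, so the analysed window starts in sequence steady state.
    """
    if level_delta <= 0:
        raise PRTSError("level_delta must be positive")
    field_symbols = np.asarray(field_symbols, dtype=int)
    if not np.isin(field_symbols, [0, 1, 2]).all():
        raise PRTSError("field symbols must be in {0, 1, 2}")
    mapped = np.vectorize(SYMBOL_MAP.get)(field_symbols)
    if warmup_duration % step_duration != 0:
        raise PRTSError("warm-up duration must be a multiple of the step duration")
    return PRTSSchedule(
        symbols=mapped,
        step_duration=step_duration,
        base_cadence=base_cadence,
        level_delta=level_delta,
        warmup_duration=warmup_duration,
    )


def default_schedule(**overrides) -> PRTSSchedule:
    """The standard degree-3 protocol: 26 symbols × 30 s = 780 s, warm-up 300 s."""
    seq = generate_ternary_msequence(degree=overrides.pop("degree", 3))
    return build_prts_schedule(seq, **overrides)


@dataclass(frozen=True)
class HarmonicSet:
    """Odd harmonics of the protocol fundamental retained for gain analysis."""

    fundamental: float
    indices: tuple[int, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(k % 2 == 0 for k in self.indices):
            raise PRTSError("harmonic indices must be odd")
        if list(self.indices) != sorted(self.indices):
            raise PRTSError("harmonic indices must be sorted ascending")
        if 1 not in self.indices:
            raise PRTSError("the fundamental (k=1) must be included")


def stimulated_harmonics(schedule: PRTSSchedule, f_max: float = 0.008) -> HarmonicSet:
    """Odd harmonics k with k/period ≤ f_max.

    The default 0.008-Hz ceiling restricts analysis to the band where oxygen
    uptake responds as a linear first-order system; for the 780-s protocol it
    keeps k ∈ {1, 3, 5}.
    """
    f1 = schedule.fundamental
    if f_max < f1:
        raise PRTSError(f"f_max {f_max} Hz below the fundamental {f1:.6f} Hz")
    k_max = int(np.floor(f_max / f1 + 1e-12))
    indices = tuple(k for k in range(1, k_max + 1) if k % 2 == 1)
    return HarmonicSet(
        fundamental=f1,
        indices=indices,
        frequencies=tuple(k * f1 for k in indices),
    )


def cadence_signal(
    schedule: PRTSSchedule, include_warmup: bool = False, rate: float = 1.0
) -> np.ndarray:
    """Realize the schedule as a piecewise-constant 1-Hz cadence series.

    Steps change at multiples of the step duration; with ``include_warmup``
    the tail of the sequence is prepended (default 300 s = 10 symbols).
    """
    reps = int(round(schedule.step_duration * rate))
    symbols = schedule.symbols
    if include_warmup:
        n_warm = int(round(schedule.warmup_duration / schedule.step_duration))
        symbols = np.concatenate([symbols[-n_warm:], symbols]) if n_warm else symbols
    return schedule.base_cadence + schedule.level_delta * np.repeat(symbols, reps).astype(float)
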