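"""Breath-print data model and the radar-plot area index (AUBP).

An electronic-nose measurement of exhaled breath is summarised as a
*breath-print* (BP): the frequency-shift magnitudes of 7 quartz-microbalance
sensors, each read at four desorption temperatures (50, 100, 150, 200 degC),
giving 28 non-negative responses per subject.

Drawn as a radar plot with one equi-angular radius per response, the profile
connecting consecutive radii encloses a polygon.  Its area — the *area under
the breath-print profile* (AUBP) — is a scalar severity index: sensor
responses fall concordantly with advancing chronic liver disease, so the
polygon (and the AUBP) shrinks from healthy controls through non-cirrhotic
disease to cirrhosis.

The enclosed area decomposes into a triangle fan about the origin: for radii
``s_1 .. s_n`` on equal angular steps ``theta = 2*pi/n``,

    A_i = (1/2) * s_i * s_{i+1} * sin(theta)      for i = 1 .. n-1
    A_0 = (1/2) * s_n * s_1   * sin(theta)        (closing triangle)

    AUBP = sum_i A_i + A_0
         = (1/2) * sin(2*pi/n) * ( sum_{i=1}^{n-1} s_i s_{i+1} + s_n s_1 )

This equals the shoelace area of the polygon with vertices
``(s_i cos(i*theta), s_i sin(i*theta))`` and is invariant to the plot's
start angle, quadratic under uniform scaling, and monotone in each radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyGroupError,
    IncompleteBreathPrintError,
    InvalidResponseError,
    LayoutMismatchError,
)

__all__ = [
    "SENSORS",
    "TEMPERATURES",
    "N_RESPONSES",
    "BreathPrint",
    "RadarLayout",
    "AUBPValue",
    "canonical_index",
    "response_columns",
    "canonical_order",
    "compute_aubp",
    "mean_profile",
]

#: Sensor numbers of the 7-element quartz-microbalance array.
SENSORS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)

#: Desorption temperatures (degC) at which each sensor is read.
TEMPERATURES: tuple[int, ...] = (50, 100, 150, 200)

#: Length of a complete breath-print.
N_RESPONSES: int = len(SENSORS) * len(TEMPERATURES)


def canonical_index(sensor: int, temperature: int) -> int:
    """Canonical position of ``(sensor, temperature)`` in a breath-print.

    Ordering is temperature-major: all 7 sensors at 50 degC, then 100,
    150, 200 degC, i.e. index ``7*t + (sensor - 1)`` with ``t`` the
    temperature-block number 0..3.  Radar plots therefore show sensors
    1..7 as contiguous runs within each temperature block.
    """
    if sensor not in SENSORS:
        raise IncompleteBreathPrintError(f"unknown sensor {sensor!r}; expected 1-7")
    if temperature not in TEMPERATURES:
        raise IncompleteBreathPrintError(
            f"unknown temperature {temperature!r}; expected one of {TEMPERATURES}"
        )
    return 7 * TEMPERATURES.index(temperature) + (sensor - 1)


def response_columns() -> list[str]:
    """Column names ``s1_t50 .. s7_t200`` in canonical order."""
    return [f"s{s}_t{t}" for t in TEMPERATURES for s in SENSORS]


def _validate_responses(values: np.ndarray, context: str = "breath-print") -> None:
    if values.ndim != 1 or values.size != N_RESPONSES:
        raise IncompleteBreathPrintError(
            f"{context} must have exactly {N_RESPONSES} responses, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        bad = int(np.flatnonzero(~np.isfinite(values))[0])
        raise InvalidResponseError(f"non-finite response at canonical index {bad}")
    if np.any(values < 0):
        bad = int(np.flatnonzero(values < 0)[0])
        raise InvalidResponseError(
            f"negative response {values[bad]!r} at canonical index {bad}; "
            "responses are frequency-shift magnitudes and must be >= 0"
        )


@dataclass(frozen=True)
class BreathPrint:
    """A complete 28-response breath-print in canonical order.

    Parameters
    ----------
    responses
        Sequence of 28 finite, non-negative sensor responses (arbitrary
        response units; the instrument reports quartz frequency shifts).
        Position ``7*t + (sensor-1)`` holds sensor ``sensor`` at
        temperature block ``t``.
    subject_id
        Opaque subject identifier.
    units
        Response units carried as metadata only; no computation depends
        on them.
    """

    responses: np.ndarray
    subject_id: str = ""
    units: str = "au"

    def __post_init__(self) -> None:
        values = np.asarray(self.responses, dtype=float)
        _validate_responses(values, context=f"breath-print {self.subject_id!r}")
        values.flags.writeable = False
        object.__setattr__(self, "responses", values)

    def response(self, sensor: int, temperature: int) -> float:
        """Response of ``sensor`` at ``temperature`` (degC)."""
        return float(self.responses[canonical_index(sensor, temperature)])

    def __len__(self) -> int:
        return int(self.responses.size)


@dataclass(frozen=True)
class RadarLayout:
    """Geometry of the radar plot: equi-angular radii on a circle.

    ``start_angle`` fixes the orientation of the first radius for
    rendering only; enclosed areas do not depend on it.
    """

    n_radii: int = N_RESPONSES
    start_angle: float = math.pi / 2

    def __post_init__(self) -> None:
        if self.n_radii < 3:
            raise LayoutMismatchError(
                f"radar layout needs >= 3 radii, got {self.n_radii}"
            )

    @property
    def angular_step(self) -> float:
        """Angle between consecutive radii, ``2*pi / n_radii``."""
        return 2.0 * math.pi / self.n_radii


@dataclass(frozen=True)
class AUBPValue:
    """Area under a breath-print profile with its triangle-fan components.

    ``components[i]`` for ``i < n-1`` is the triangle ``A_{i+1}`` between
    consecutive radii ``s_{i+1}`` and ``s_{i+2}`` (1-based); the last entry
    is the closing triangle ``A_0`` between the last and first radius.
    """

    area: float
    components: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        comps.flags.writeable = False
        object.__setattr__(self, "components", comps)


def canonical_order(
    raw_row: Mapping[tuple[int, int], float], subject_id: str = ""
) -> BreathPrint:
    """Assemble a :class:`BreathPrint` from ``(sensor, temperature) -> response``.

    Raises
    ------
    IncompleteBreathPrintError
        If any of the 28 pairs is absent (the message names the pair).
    InvalidResponseError
        If a response is negative or non-finite.
    """
    values = np.empty(N_RESPONSES, dtype=float)
    for t in TEMPERATURES:
        for s in SENSORS:
            try:
                values[canonical_index(s, t)] = float(raw_row[(s, t)])
            except KeyError:
                raise IncompleteBreathPrintError(
                    f"incomplete breath-print: missing response for "
                    f"sensor {s} at {t} degC"
                ) from None
    return BreathPrint(responses=values, subject_id=subject_id)


def compute_aubp(bp: BreathPrint | Sequence[float], layout: RadarLayout | None = None) -> AUBPValue:
    """Area enclosed by the breath-print profile on the radar plot.

    Computed as the triangle fan ``A_1 .. A_{n-1}`` between consecutive
    radii plus the closing triangle ``A_0`` between the last and first
    radius (see module docstring).  The result carries squared response
    units.

    Raises
    ------
    LayoutMismatchError
        If ``layout.n_radii`` differs from the number of responses.
    """
    values = bp.responses if isinstance(bp, BreathPrint) else np.asarray(bp, dtype=float)
    if layout is None:
        layout = RadarLayout(n_radii=values.size) if values.size != N_RESPONSES else RadarLayout()
    if layout.n_radii != values.size:
        raise LayoutMismatchError(
            f"layout has {layout.n_radii} radii but breath-print has "
            f"{values.size} responses"
        )
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise InvalidResponseError("responses must be finite and >= 0")
    half_sin = 0.5 * math.sin(layout.angular_step)
    components = half_sin * values * np.roll(values, -1)
    return AUBPValue(area=float(components.sum()), components=components)


def mean_profile(bps: Iterable[BreathPrint]) -> BreathPrint:
    """Element-wise mean breath-print of a non-empty group.

    Used for group-level radar-plot summaries (e.g. the mean profile of a
    diagnostic class).
    """
    stack = [bp.responses for bp in bps]
    if not stack:
        raise EmptyGroupError("cannot average an empty group of breath-prints")
    mean = np.mean(np.stack(stack), axis=0)
    return BreathPrint(responses=mean, subject_id=f"mean_of_{len(stack)}")
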