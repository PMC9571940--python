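"""Electrode geometry and measurement schedules for EIT drive patterns.

An eight-electrode ring (labels A..H, counterclockwise from angle 0) is
driven either with the traditional cyclic adjacent excitation, or with one
of four *fixed* excitation patterns in which a single electrode pair
injects current for the whole gesture while passive adjacent pairs are
measured cyclically.  Every pattern yields exactly 40 measurements per
dynamic gesture.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeRing",
    "DrivePattern",
    "MeasurementSchedule",
    "PATTERN_NAMES",
    "build_ring",
    "get_pattern",
    "build_schedule",
    "schedule_to_frame",
]

Pair = tuple[int, int]


@dataclass(frozen=True)
class ElectrodeRing:
    """Equally spaced electrodes on the boundary of the arm cross-section.

    Angles are electrode centers in radians, strictly increasing in
    [0, 2*pi), with electrode ``A`` at angle 0 and ordering counterclockwise.
    """

    n_electrodes: int
    labels: tuple[str, ...]
    angles: np.ndarray

    @property
    def spacing(self) -> float:
        """Angular spacing between neighbouring electrode centers."""
        return 2.0 * np.pi / self.n_electrodes

    def label_of(self, index: int) -> str:
        return self.labels[index]


def build_ring(n_electrodes: int = 8) -> ElectrodeRing:
    """Build a uniformly spaced electrode ring.

    Parameters
    ----------
    n_electrodes:
        Number of electrodes; must be even and at least 4.
    """
    if n_electrodes < 4 or n_electrodes % 2 != 0:
        raise ValueError(
            f"electrode count must be even and >= 4, got {n_electrodes}"
        )
    labels = tuple(string.ascii_uppercase[i] for i in range(n_electrodes))
    angles = 2.0 * np.pi * np.arange(n_electrodes) / n_electrodes
    return ElectrodeRing(n_electrodes=n_electrodes, labels=labels, angles=angles)


@dataclass(frozen=True)
class DrivePattern:
    """One excitation drive pattern.

    ``excitation_pairs[k]`` is the current-injection pair active during
    cycle block ``k``; ``measurement_pairs_per_excitation[k]`` lists the
    passive electrode pairs measured under that excitation, in order.
    Fixed patterns have a single excitation pair repeated for ``n_cycles``
    cycles; the cyclic pattern advances the excitation pair each block.
    """

    name: str
    excitation_pairs: tuple[Pair, ...]
    measurement_pairs_per_excitation: tuple[tuple[Pair, ...], ...]
    n_cycles: int

    def __post_init__(self) -> None:
        for exc, meas_list in zip(
            self.excitation_pairs, self.measurement_pairs_per_excitation
        ):
            for meas in meas_list:
                if set(exc) & set(meas):
                    raise ValueError(
                        f"measurement pair {meas} shares an electrode with "
                        f"excitation pair {exc} in pattern {self.name!r}"
                    )


@dataclass(frozen=True)
class MeasurementSchedule:
    """Ordered (excitation pair, measurement pair, time index) steps."""

    pattern_name: str
    steps: tuple[tuple[Pair, Pair, int], ...]

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self) -> Iterator[tuple[Pair, Pair, int]]:
        return iter(self.steps)


def _adjacent_pairs_excluding(n: int, exc: Pair) -> tuple[Pair, ...]:
    """Adjacent pairs (j, j+1 mod n) containing no excitation electrode,
    in ascending order of the first electrode."""
    out = []
    for j in range(n):
        pair = (j, (j + 1) % n)
        if not (set(pair) & set(exc)):
            out.append(pair)
    return tuple(out)


def _fixed(name: str, exc: Pair, meas: tuple[Pair, ...], cycles: int) -> DrivePattern:
    return DrivePattern(
        name=name,
        excitation_pairs=(exc,),
        measurement_pairs_per_excitation=(meas,),
        n_cycles=cycles,
    )


def _cyclic_adjacent(n: int = 8) -> DrivePattern:
    excs = tuple((k, (k + 1) % n) for k in range(n))
    meas = tuple(_adjacent_pairs_excluding(n, exc) for exc in excs)
    return DrivePattern(
        name="cyclic_adjacent",
        excitation_pairs=excs,
        measurement_pairs_per_excitation=meas,
        n_cycles=1,
    )


# Drive-pattern table for the 8-electrode system.  A=0 ... H=7.
_PATTERNS: dict[str, DrivePattern] = {
    "cyclic_adjacent": _cyclic_adjacent(8),
    "fixed_adjacent": _fixed(
        "fixed_adjacent", (0, 1), ((2, 3), (3, 4), (4, 5), (5, 6), (6, 7)), 8
    ),
    "fixed_interval_1": _fixed(
        "fixed_interval_1", (0, 2), ((3, 4), (4, 5), (5, 6), (6, 7)), 10
    ),
    "fixed_interval_2": _fixed(
        "fixed_interval_2", (0, 3), ((1, 2), (4, 5), (5, 6), (6, 7)), 10
    ),
    "fixed_opposite": _fixed(
        "fixed_opposite", (0, 4), ((1, 2), (2, 3), (5, 6), (6, 7)), 10
    ),
}

PATTERN_NAMES: tuple[str, ...] = tuple(_PATTERNS)


def get_pattern(name: str) -> DrivePattern:
    """Look up one of the five named drive patterns."""
    try:
        return _PATTERNS[name]
    except KeyError:
        raise ValueError(
            f"unknown drive pattern {name!r}; expected one of {PATTERN_NAMES}"
        ) from None


def build_schedule(pattern: DrivePattern | str) -> MeasurementSchedule:
    """Expand a drive pattern into its ordered 40-step measurement schedule.

    Each step is one time sample of the evolving gesture.  Fixed patterns
    repeat their measurement cycle ``n_cycles`` times under the constant
    excitation pair; the cyclic pattern advances the excitation pair each
    block and measures the five qualifying adjacent passive pairs.
    """
    if isinstance(pattern, str):
        pattern = get_pattern(pattern)
    steps: list[tuple[Pair, Pair, int]] = []
    t = 0
    for _ in range(pattern.n_cycles):
        for exc, meas_list in zip(
            pattern.excitation_pairs, pattern.measurement_pairs_per_excitation
        ):
            for meas in meas_list:
                steps.append((exc, meas, t))
                t += 1
    return MeasurementSchedule(pattern_name=pattern.name, steps=tuple(steps))


def schedule_to_frame(
    schedule: MeasurementSchedule, ring: ElectrodeRing | None = None
) -> pd.DataFrame:
    """Tabulate a schedule with electrode labels (columns step, exc_a,
    exc_b, meas_a, meas_b), suitable for CSV export."""
    ring = ring or build_ring(8)
    rows = [
        {
            "step": t,
            "exc_a": ring.label_of(exc[0]),
            "exc_b": ring.label_of(exc[1]),
            "meas_a": ring.label_of(meas[0]),
            "meas_b": ring.label_of(meas[1]),
        }
        for exc, meas, t in schedule
    ]
    return pd.DataFrame(rows)
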