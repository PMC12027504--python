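"""Temperature-programmed (linear) retention indices against an n-alkane ladder.

Under a linear temperature programme the retention index of a peak at
time ``t`` bracketed by n-alkanes with ``n`` and ``n + k`` carbons is

    RI = 100*n + 100*k * (t - t_n) / (t_{n+k} - t_n)

(the van den Dool-Kratz formulation; ``k > 1`` handles gaps in the
standard mix).  Indices are rounded half-up to the nearest integer.
Peaks eluting outside the ladder raise by default; nearest-segment
linear extrapolation is available explicitly via ``extrapolate=True``
and is flagged, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .compounds import CHCClass, ComponentNameError, parse_component_name

__all__ = [
    "AlkaneLadder",
    "LadderError",
    "ExtrapolationError",
    "retention_index",
    "retention_time_for_index",
    "build_ladder",
]


class LadderError(ValueError):
    """Invalid n-alkane ladder (too short or non-monotone)."""


class ExtrapolationError(ValueError):
    """Retention time outside the ladder range without ``extrapolate=True``."""


@dataclass(frozen=True)
class AlkaneLadder:
    """n-alkane calibration ladder: carbon number -> retention time (min)."""

    carbons: tuple[int, ...]
    times: tuple[float, ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "AlkaneLadder":
        items = sorted(mapping.items())
        ladder = cls(tuple(c for c, _ in items), tuple(t for _, t in items))
        ladder.validate()
        return ladder

    def validate(self) -> None:
        if len(self.carbons) < 2:
            raise LadderError("ladder needs at least two n-alkanes")
        if any(b <= a for a, b in zip(self.carbons, self.carbons[1:])):
            raise LadderError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise LadderError("retention times must increase with carbon number")

    @property
    def t_min(self) -> float:
        return self.times[0]

    @property
    def t_max(self) -> float:
        return self.times[-1]

    def segment_for(self, t: float) -> int:
        """Index i of the ladder segment [i, i+1] bracketing (or nearest to) t."""
        for i in range(len(self.carbons) - 1):
            if t <= self.times[i + 1]:
                return max(i, 0)
        return len(self.carbons) - 2


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def retention_index(t: float, ladder: AlkaneLadder, *, extrapolate: bool = False) -> int:
    """Linear retention index of a peak at ``t`` minutes.

    Raises :class:`ExtrapolationError` for ``t`` outside the ladder
    unless ``extrapolate=True``, in which case the nearest ladder
    segment is extended linearly.
    """
    ladder.validate()
    if not extrapolate and not (ladder.t_min <= t <= ladder.t_max):
        raise ExtrapolationError(
            f"t={t} min outside ladder range [{ladder.t_min}, {ladder.t_max}]; "
            "pass extrapolate=True to extend the nearest segment"
        )
    i = ladder.segment_for(t)
    n, t_n = ladder.carbons[i], ladder.times[i]
    n2, t_n2 = ladder.carbons[i + 1], ladder.times[i + 1]
    k = n2 - n
    ri = 100.0 * n + 100.0 * k * (t - t_n) / (t_n2 - t_n)
    return _round_half_up(ri)


def retention_time_for_index(ri: float, ladder: AlkaneLadder) -> float:
    """Inverse interpolation: retention time whose index equals ``ri``.

    Extends the nearest segment linearly for indices outside the ladder
    (used by the synthetic-data generator to place peaks).
    """
    ladder.validate()
    # choose segment by index rather than time
    idx = [100 * c for c in ladder.carbons]
    i = 0
    for j in range(len(idx) - 1):
        if ri <= idx[j + 1]:
            i = j
            break
    else:
        i = len(idx) - 2
    frac = (ri - idx[i]) / (idx[i + 1] - idx[i])
    return ladder.times[i] + frac * (ladder.times[i + 1] - ladder.times[i])


def build_ladder(components: Iterable[tuple[str, float]]) -> AlkaneLadder:
    """Build a ladder from identified n-alkane peaks.

    Parameters
    ----------
    components:
        Iterable of ``(label, retention_time)``; labels that parse to
        n-alkanes are used, all others ignored.  Order-independent.
    """
    mapping: dict[int, float] = {}
    for label, rt in components:
        try:
            c = parse_component_name(str(label))
        except ComponentNameError:
            continue
        if c.chc_class != CHCClass.N_ALKANE:
            continue
        if c.chain_length in mapping and mapping[c.chain_length] != rt:
            raise LadderError(f"conflicting retention times for n-C{c.chain_length}")
        mapping[c.chain_length] = float(rt)
    if len(mapping) < 2:
        raise LadderError("need at least two identified n-alkanes to build a ladder")
    return AlkaneLadder.from_mapping(mapping)
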