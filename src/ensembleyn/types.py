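"""Domain types for the Yes/No ensemble-perception task.

The task: a memory display of 64 bars carries exactly two "old" feature
values drawn from a 7-step series (orientations in 15-degree steps, or one
of two 7-level luminance series).  A single probe then carries either the
never-shown mean of the two old values (M), one of the old values (O), or a
novel value outside the old range (N).  The participant answers Yes ("the
probe's value was present") or No.

All positions are 1-based indices into the 7-level series; all distances
are ordinal steps along the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

ORIENTATION_LEVELS: Tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0)

DIMENSIONS = ("orientation", "color")
FAMILIES = {
    "orientation": ("rightward", "leftward"),
    "color": ("green", "blue"),
}
PROBE_CLASSES = ("M", "O", "N")
RESPONSES = ("Yes", "No")

N_SERIES_LEVELS = 7


@dataclass(frozen=True)
class FeatureSeries:
    """One 7-level feature series (a tilt direction or a hue family).

    ``levels`` are the physical feature values in series order (degrees for
    orientation, CIE Y luminance for color); ``labels`` are optional display
    labels (sRGB hex strings for the color series).  One series step is the
    ordinal unit of all probe distances.
    """

    dimension: str
    family: str
    levels: Tuple[float, ...]
    labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension: {self.dimension!r}")
        if self.family not in FAMILIES[self.dimension]:
            raise ValueError(
                f"unknown family {self.family!r} for dimension {self.dimension!r}"
            )
        if len(self.levels) != N_SERIES_LEVELS:
            raise ValueError(f"series must have {N_SERIES_LEVELS} levels")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("series levels must be strictly increasing")
        if self.labels is not None and len(self.labels) != N_SERIES_LEVELS:
            raise ValueError("labels must match the number of levels")


@dataclass(frozen=True)
class OldPair:
    """The two old values shown in a memory display, two steps apart.

    The intervening series position is the (never-shown) mean value.
    """

    lower_index: int
    upper_index: int
    mean_index: int

    def __post_init__(self) -> None:
        if not 1 <= self.lower_index <= N_SERIES_LEVELS - 2:
            raise ValueError("lower_index must lie in 1..5")
        if self.upper_index != self.lower_index + 2:
            raise ValueError("old values must be exactly two steps apart")
        if self.mean_index != self.lower_index + 1:
            raise ValueError("mean_index must be the intervening position")

    @classmethod
    def from_lower(cls, lower_index: int) -> "OldPair":
        return cls(lower_index, lower_index + 2, lower_index + 1)

    @property
    def indices(self) -> Tuple[int, int]:
        return (self.lower_index, self.upper_index)


@dataclass(frozen=True)
class ProbeSpec:
    """A probe on one feature dimension, with its two ordinal distances.

    ``dist_from_mean`` grounds the perceptual-averaging classification,
    ``dist_from_nearest_old`` the similarity classification.  ``side`` marks
    whether an N probe falls below or above the old range (M and O probes
    get ``"n/a"``).
    """

    probe_class: str
    series_index: int
    dist_from_mean: int
    dist_from_nearest_old: int
    side: str = "n/a"

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class: {self.probe_class!r}")
        if not 1 <= self.series_index <= N_SERIES_LEVELS:
            raise ValueError("series_index out of range")
        if self.probe_class == "M":
            if (self.dist_from_mean, self.dist_from_nearest_old) != (0, 1):
                raise ValueError("M probe must have distances (0, 1)")
        elif self.probe_class == "O":
            if (self.dist_from_mean, self.dist_from_nearest_old) != (1, 0):
                raise ValueError("O probe must have distances (1, 0)")
        else:
            if self.dist_from_nearest_old not in (1, 2, 3, 4):
                raise ValueError("N probe must lie 1..4 steps from the nearest old")
            if self.dist_from_mean != self.dist_from_nearest_old + 1:
                raise ValueError("N probe distances must satisfy d_mean = d_old + 1")
            if self.side not in ("below", "above"):
                raise ValueError("N probe must carry a side (below/above)")


@dataclass(frozen=True)
class Trial:
    """One memory display + probe.

    Experiments 1-2 manipulate a single (relevant) dimension; experiments
    3-4 additionally carry a full probe manipulation on the irrelevant
    dimension (the one the participant is told to ignore).
    """

    experiment: int
    block: int
    trial_index: int
    practice: bool
    relevant_dimension: str
    relevant_series: FeatureSeries
    relevant_old: OldPair
    relevant_probe: ProbeSpec
    irrelevant_series: Optional[FeatureSeries] = None
    irrelevant_old: Optional[OldPair] = None
    irrelevant_probe: Optional[ProbeSpec] = None
    layout_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2, 3, 4):
            raise ValueError("experiment must be 1..4")
        two_dim = self.experiment in (3, 4)
        has_irr = self.irrelevant_probe is not None
        if two_dim and not has_irr:
            raise ValueError("experiments 3-4 require an irrelevant-dimension probe")
        if not two_dim and has_irr:
            raise ValueError("experiments 1-2 carry no irrelevant-dimension probe")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of a synthetic observer.

    Two response rules are available:

    * ``averaging`` -- p(No) follows the three-parameter log-logistic
      ``a + (1 - a) / (1 + exp(b - c*x))`` of the probe's ordinal distance
      ``x`` from the mean.  ``a`` is the floor rejection rate.
    * ``similarity`` -- confusions with the two old items are independent:
      ``p(No) = prod_i (1 - g(d_i))`` where ``d_i`` is the probe's ordinal
      distance from old item ``i`` and ``g`` is a non-increasing confusion
      kernel (``kernel[d]``; zero beyond the tuple's support).

    For two-dimension experiments the response mixes the relevant-dimension
    p(No) with an irrelevant-dimension p(No) with weight ``lam``; the
    irrelevant dimension uses ``irrelevant`` (defaults to these same
    parameters).
    """

    rule: str
    a: float = 0.2
    b: float = 0.0
    c: float = 1.0
    kernel: Tuple[float, ...] = (0.6, 0.3, 0.0)
    lam: float = 0.15
    irrelevant: Optional["ObserverParams"] = None

    def __post_init__(self) -> None:
        if self.rule not in ("averaging", "similarity"):
            raise ValueError(f"unknown observer rule: {self.rule!r}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must lie in [0, 1]")
        if self.c < 0.0:
            raise ValueError("c must be non-negative")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if any(not 0.0 <= g <= 1.0 for g in self.kernel):
            raise ValueError("kernel values must lie in [0, 1]")
        if any(g2 > g1 for g1, g2 in zip(self.kernel, self.kernel[1:])):
            raise ValueError("kernel must be non-increasing in distance")

    def g(self, d: int) -> float:
        """Confusion probability at ordinal distance ``d`` (0 beyond support)."""
        if d < 0:
            raise ValueError("distance must be non-negative")
        return self.kernel[d] if d < len(self.kernel) else 0.0


@dataclass(frozen=True)
class ResponseRecord:
    """A trial together with one participant's Yes/No response."""

    participant_id: str
    trial: Trial
    response: str

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"response must be Yes or No, got {self.response!r}")
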