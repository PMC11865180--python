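"""Named observer parameterizations and their category probabilities.

``EXP1_AVERAGING`` is an averaging observer whose log-logistic parameters
are anchored to the orientation experiment's marginal means (p(No) of
about 0.22 / 0.30 / 0.56 for the Mean, Old and N1 probes).
``EXP2_SIMILARITY`` is a similarity observer with a truncated confusion
kernel (g(d) = 0 for d >= 3) whose Old-probe rejection rate matches the
color experiment's (about 0.25); truncation makes the similarity product
prediction for the mean probe exact.
"""

from __future__ import annotations

from typing import Dict

from .psychometric_fit import loglogistic
from .types import ObserverParams

EXP1_AVERAGING = ObserverParams(rule="averaging", a=0.2, b=3.6, c=1.7)
EXP2_SIMILARITY = ObserverParams(rule="similarity", kernel=(0.72, 0.35, 0.10, 0.0))

OBSERVER_PRESETS: Dict[str, ObserverParams] = {
    "exp1": EXP1_AVERAGING,
    "exp2": EXP2_SIMILARITY,
}

#: Probe-type category -> (distance from mean, distances to the two old items)
PROBE_GEOMETRY = {
    "M": (0, (1, 1)),
    "Old": (1, (0, 2)),
    "N1": (2, (1, 3)),
    "N2": (3, (2, 4)),
    "N3": (4, (3, 5)),
    "N4": (5, (4, 6)),
}


def category_probabilities(params: ObserverParams) -> Dict[str, float]:
    """True p(No) per probe-type category under an observer model.

    Categories are the six probe types (M, Old, N1..N4); each has a unique
    pair of ordinal distances, so both classificatory schemes are
    recoverable from these probabilities.
    """
    out = {}
    for cat, (d_mean, d_olds) in PROBE_GEOMETRY.items():
        if params.rule == "averaging":
            out[cat] = float(loglogistic(d_mean, params.a, params.b, params.c))
        else:
            p = 1.0
            for d in d_olds:
                p *= 1.0 - params.g(d)
            out[cat] = p
    return out
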