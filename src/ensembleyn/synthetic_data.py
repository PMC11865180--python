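"""Synthetic sessions and observers for the Yes/No ensemble task.

Generates trial sequences matching the four experimental designs and
simulates Yes/No responses from parameterized observers, so that every
analysis stage can be exercised on data whose generating process is known.

Design summary:

* Experiments 1 (judge orientation) and 2 (judge color): 480 experimental
  trials per session -- 240 O probes, 120 M, 120 N -- preceded by 20
  flagged practice trials, shuffled into five blocks of 96.  The series
  family (tilt direction or hue) is balanced half/half across trials.
* Experiments 3 (judge color, orientation varies) and 4 (judge
  orientation, color varies): a 3x3 factorial of probe class on the
  relevant and irrelevant dimensions; 80 trials per cell when the relevant
  probe is O, 40 otherwise (480 total), plus 20 practice trials.

Randomness contract: one root seed per session is split into independent
sub-streams for design, layout and responses, so the trial sequence is
invariant to the observer model used to answer it.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptives import classify
from .psychometric_fit import loglogistic
from .types import (
    FAMILIES,
    N_SERIES_LEVELS,
    ORIENTATION_LEVELS,
    FeatureSeries,
    ObserverParams,
    OldPair,
    ProbeSpec,
    ResponseRecord,
    Trial,
)

#: Stimulus geometry (pixels): bar field and central exclusion disc.
REGION_WIDTH = 1000
REGION_HEIGHT = 800
BAR_LENGTH = 40
N_BARS = 64

#: Experimental trial counts for the single-dimension designs.
SINGLE_DIM_COUNTS = {"O": 240, "M": 120, "N": 120}
#: Per-cell counts (relevant class -> per irrelevant class) for Exps 3-4.
FACTORIAL_COUNTS = {"O": 80, "M": 40, "N": 40}
N_PRACTICE = 20
N_BLOCKS = 5
BLOCK_SIZE = 96

RELEVANT_DIMENSION = {1: "orientation", 2: "color", 3: "color", 4: "orientation"}
IRRELEVANT_DIMENSION = {3: "orientation", 4: "color"}


@lru_cache(maxsize=None)
def _color_table() -> pd.DataFrame:
    path = importlib.resources.files("ensembleyn") / "data" / "color_series.csv"
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p)


def make_series(dimension: str, family: str) -> FeatureSeries:
    """The canonical 7-level series for a dimension/family combination.

    Orientation series run 0-90 degrees in 15-degree steps; color series
    are the packaged luminance ladders of the green and blue hue families
    (levels are CIE Y, labels the sRGB hex values).
    """
    if dimension not in FAMILIES:
        raise ValueError(f"unknown dimension: {dimension!r}")
    if family not in FAMILIES[dimension]:
        raise ValueError(f"unknown family {family!r} for dimension {dimension!r}")
    if dimension == "orientation":
        return FeatureSeries(dimension, family, ORIENTATION_LEVELS)
    tab = _color_table()
    sub = tab.loc[tab["family"] == family].sort_values("level")
    return FeatureSeries(
        dimension,
        family,
        tuple(float(v) for v in sub["Y"]),
        labels=tuple(sub["hex"]),
    )


def sample_old_pair(series: FeatureSeries, rng: np.random.Generator) -> OldPair:
    """Draw two old values two steps apart, uniformly over positions."""
    lower = int(rng.integers(1, N_SERIES_LEVELS - 1))  # 1..5
    return OldPair.from_lower(lower)


def assign_probe(
    probe_class: str,
    old: OldPair,
    series: FeatureSeries,
    rng: np.random.Generator,
) -> ProbeSpec:
    """Select the probe position for a trial of the given class.

    M is the mean position; O is one of the two old positions (uniform);
    N is uniform over the four series positions outside the old range and
    the mean.
    """
    if probe_class == "M":
        idx = old.mean_index
    elif probe_class == "O":
        idx = int(rng.choice(old.indices))
    elif probe_class == "N":
        excluded = {old.lower_index, old.mean_index, old.upper_index}
        candidates = [i for i in range(1, N_SERIES_LEVELS + 1) if i not in excluded]
        idx = int(rng.choice(candidates))
    else:
        raise ValueError(f"unknown probe class: {probe_class!r}")
    d_mean, d_old = classify(old, idx)
    if probe_class == "N":
        side = "below" if idx < old.lower_index else "above"
    else:
        side = "n/a"
    return ProbeSpec(probe_class, idx, d_mean, d_old, side)


def _balanced_families(dimension: str, n: int, rng: np.random.Generator) -> List[str]:
    fams = FAMILIES[dimension]
    seq = [fams[0]] * (n // 2) + [fams[1]] * (n - n // 2)
    return [seq[i] for i in rng.permutation(n)]


def _dimension_draw(
    dimension: str, family: str, probe_class: str, rng: np.random.Generator
) -> Tuple[FeatureSeries, OldPair, ProbeSpec]:
    series = make_series(dimension, family)
    old = sample_old_pair(series, rng)
    probe = assign_probe(probe_class, old, series, rng)
    return series, old, probe


def _session_streams(seed: int) -> Tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    design_ss, layout_ss, response_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(design_ss),
        np.random.default_rng(layout_ss),
        np.random.default_rng(response_ss),
    )


def generate_session(experiment: int, participant_id: str, seed: int) -> List[Trial]:
    """The full trial list (practice + experimental) for one session.

    Deterministic given ``seed``; the layout seeds stored on the trials
    come from a dedicated sub-stream so layouts are reproducible too.
    """
    if experiment not in (1, 2, 3, 4):
        raise ValueError("experiment must be 1..4")
    rng, layout_rng, _ = _session_streams(seed)
    rel_dim = RELEVANT_DIMENSION[experiment]

    if experiment in (1, 2):
        classes = [c for c, n in SINGLE_DIM_COUNTS.items() for _ in range(n)]
        cells: List[Tuple[str, Optional[str]]] = [(c, None) for c in classes]
        practice_cells = [("O", None)] * 10 + [("M", None)] * 5 + [("N", None)] * 5
    else:
        cells = [
            (rel, irr)
            for rel, n in FACTORIAL_COUNTS.items()
            for irr in ("M", "O", "N")
            for _ in range(n)
        ]
        cell_ids = rng.choice(len(cells), size=N_PRACTICE, replace=False)
        practice_cells = [cells[i] for i in cell_ids]

    order = rng.permutation(len(cells))
    cells = [cells[i] for i in order]
    rel_families = _balanced_families(rel_dim, len(cells), rng)
    if experiment in (3, 4):
        irr_dim = IRRELEVANT_DIMENSION[experiment]
        irr_families = _balanced_families(irr_dim, len(cells), rng)

    trials: List[Trial] = []

    def build(i: int, rel_cls: str, irr_cls: Optional[str], practice: bool,
              rel_family: str, irr_family: Optional[str]) -> Trial:
        rel = _dimension_draw(rel_dim, rel_family, rel_cls, rng)
        irr = (
            _dimension_draw(IRRELEVANT_DIMENSION[experiment], irr_family, irr_cls, rng)
            if irr_cls is not None
            else (None, None, None)
        )
        block = 0 if practice else 1 + (i - 1) // BLOCK_SIZE
        return Trial(
            experiment=experiment,
            block=block,
            trial_index=i,
            practice=practice,
            relevant_dimension=rel_dim,
            relevant_series=rel[0],
            relevant_old=rel[1],
            relevant_probe=rel[2],
            irrelevant_series=irr[0],
            irrelevant_old=irr[1],
            irrelevant_probe=irr[2],
            layout_seed=int(layout_rng.integers(0, 2**31 - 1)),
        )

    practice_order = rng.permutation(len(practice_cells))
    practice_cells = [practice_cells[i] for i in practice_order]
    p_rel_fams = _balanced_families(rel_dim, N_PRACTICE, rng)
    p_irr_fams = (
        _balanced_families(IRRELEVANT_DIMENSION[experiment], N_PRACTICE, rng)
        if experiment in (3, 4)
        else [None] * N_PRACTICE
    )
    for i, (rel_cls, irr_cls) in enumerate(practice_cells):
        trials.append(build(i - N_PRACTICE, rel_cls, irr_cls, True, p_rel_fams[i], p_irr_fams[i]))
    for i, (rel_cls, irr_cls) in enumerate(cells, start=1):
        irr_family = irr_families[i - 1] if experiment in (3, 4) else None
        trials.append(build(i, rel_cls, irr_cls, False, rel_families[i - 1], irr_family))
    return trials


def generate_layout(trial: Trial, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Bar positions and feature assignments for one memory display.

    64 bars are placed uniformly in the 1000x800 px field, with bar centers
    kept outside a central disc of radius one bar length (40 px) so no
    memory bar superimposes on the later central probe.  Exactly half the
    bars carry each old value; in the two-dimension experiments the four
    old-orientation x old-color combinations get 16 bars each.
    """
    if rng is None:
        rng = np.random.default_rng(trial.layout_seed)
    xs = np.empty(N_BARS)
    ys = np.empty(N_BARS)
    half_w, half_h = REGION_WIDTH / 2, REGION_HEIGHT / 2
    for i in range(N_BARS):
        while True:
            x = rng.uniform(-half_w, half_w)
            y = rng.uniform(-half_h, half_h)
            if x * x + y * y > BAR_LENGTH**2:
                xs[i], ys[i] = x, y
                break

    rel_vals = [trial.relevant_series.levels[j - 1] for j in trial.relevant_old.indices]
    rel_assign = np.repeat([0, 1], N_BARS // 2)
    out = pd.DataFrame(
        {
            "x": xs,
            "y": ys,
            trial.relevant_dimension: [rel_vals[k] for k in rel_assign],
        }
    )
    if trial.irrelevant_old is not None:
        irr_vals = [
            trial.irrelevant_series.levels[j - 1] for j in trial.irrelevant_old.indices
        ]
        # balanced crossing: 16 bars per old-value combination
        irr_assign = np.tile(np.repeat([0, 1], N_BARS // 4), 2)
        out[trial.irrelevant_series.dimension] = [irr_vals[k] for k in irr_assign]
    perm = rng.permutation(N_BARS)
    return out.iloc[perm].reset_index(drop=True)


def _rule_p_no(probe: ProbeSpec, old: OldPair, params: ObserverParams) -> float:
    if params.rule == "averaging":
        return float(loglogistic(probe.dist_from_mean, params.a, params.b, params.c))
    p = 1.0
    for old_idx in old.indices:
        d = abs(probe.series_index - old_idx)
        p *= 1.0 - params.g(d)
    return p


def response_probability(trial: Trial, params: ObserverParams) -> float:
    """The observer's p(No) for a trial.

    Single-dimension trials use the relevant rule directly; two-dimension
    trials mix in an irrelevant-dimension p(No) with weight ``params.lam``.
    """
    p = _rule_p_no(trial.relevant_probe, trial.relevant_old, params)
    if trial.irrelevant_probe is not None:
        irr_params = params.irrelevant if params.irrelevant is not None else params
        p_irr = _rule_p_no(trial.irrelevant_probe, trial.irrelevant_old, irr_params)
        p = (1.0 - params.lam) * p + params.lam * p_irr
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"invalid response probability {p}")
    return p


def simulate_response(
    trial: Trial,
    params: ObserverParams,
    rng: np.random.Generator,
    participant_id: str = "sim",
) -> ResponseRecord:
    """One binomial Yes/No draw from the observer model."""
    p_no = response_probability(trial, params)
    response = "No" if rng.random() < p_no else "Yes"
    return ResponseRecord(participant_id, trial, response)


def simulate_session(
    experiment: int,
    participant_id: str,
    params: ObserverParams,
    seed: int,
) -> List[ResponseRecord]:
    """Design + responses for one participant, from one root seed.

    The design stream is identical to :func:`generate_session` with the
    same seed, so changing the observer never perturbs the trial sequence.
    """
    trials = generate_session(experiment, participant_id, seed)
    _, _, response_rng = _session_streams(seed)
    return [
        simulate_response(t, params, response_rng, participant_id) for t in trials
    ]


def simulate_experiment(
    experiment: int,
    params: ObserverParams,
    n_participants: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate a whole experiment; returns the canonical trial table."""
    from .data_io import records_to_table

    child_seeds = np.random.SeedSequence(seed).generate_state(n_participants)
    records: List[ResponseRecord] = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        records.extend(
            simulate_session(experiment, pid, params, int(child_seeds[i] % (2**31 - 1)))
        )
    return records_to_table(records)
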