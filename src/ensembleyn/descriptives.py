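"""Probe classification, per-participant p(No) tables, exclusions, and the
similarity point prediction.

Two classificatory schemes exist for the same trials:

* ``from_mean`` -- ordinal distance of the probe from the (never shown)
  mean value: M probes sit at x=0, O probes at x=1, N probes at x=2..5.
* ``from_old`` -- ordinal distance from the nearest old item: O probes sit
  at x=0, M and N1 probes both at x=1 (they are equidistant from the old
  items and are kept as separate rows so downstream code can pool or not),
  N2..N4 at x=2..4.

The similarity point prediction uses the two distance-1 N probes: if
confusions with the two old items are independent and the mean probe is
exactly as confusable as each N1 probe, then

    p(No|M)_similarity = p(No|N1A) * p(No|N1B)

equivalently p(Yes|M) = p(Yes|N1A) + p(Yes|N1B) - p(Yes|N1A)*p(Yes|N1B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .types import OldPair

logger = logging.getLogger(__name__)

FROM_MEAN = "from_mean"
FROM_OLD = "from_old"
SCHEMES = (FROM_MEAN, FROM_OLD)


def classify(old: OldPair, probe_index: int) -> Tuple[int, int]:
    """Ordinal (distance-from-mean, distance-from-nearest-old) of a probe."""
    if not 1 <= probe_index <= 7:
        raise ValueError("probe index out of series range")
    d_mean = abs(probe_index - old.mean_index)
    d_old = min(abs(probe_index - old.lower_index), abs(probe_index - old.upper_index))
    return d_mean, d_old


def _drop_practice(trials: pd.DataFrame) -> pd.DataFrame:
    if "practice_flag" in trials.columns:
        return trials.loc[~trials["practice_flag"].astype(bool)]
    return trials


def _category_label(scheme: str, probe_class: str, d_mean: int, d_old: int) -> str:
    if probe_class == "M":
        return "M"
    if probe_class == "O":
        return "Old"
    return f"N{d_old}"


def condition_table(trials: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Per-category No-response proportions for one participant.

    ``trials`` holds one participant's rows of the canonical trial table
    (practice rows are dropped here).  Returns a frame with columns
    ``participant_id, scheme, x, category, n_trials, n_no, p_no`` where
    ``p_no`` is the exact ratio of No responses.  Categories with no trials
    are simply absent (flagged by a log message), never imputed.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme: {scheme!r}")
    df = _drop_practice(trials)
    if df.empty:
        raise ValueError("no analyzable trials")
    pid = str(df["participant_id"].iloc[0])

    if scheme == FROM_MEAN:
        x = df["relevant_dist_from_mean"].astype(int)
        expected = set(range(6))
    else:
        x = df["relevant_dist_from_old"].astype(int)
        expected = set(range(5))

    work = pd.DataFrame(
        {
            "x": x,
            "category": [
                _category_label(scheme, pc, dm, do)
                for pc, dm, do in zip(
                    df["relevant_probe_class"],
                    df["relevant_dist_from_mean"].astype(int),
                    df["relevant_dist_from_old"].astype(int),
                )
            ],
            "no": (df["response"] == "No").astype(int),
        }
    )
    out = (
        work.groupby(["x", "category"], as_index=False)
        .agg(n_trials=("no", "size"), n_no=("no", "sum"))
        .sort_values(["x", "category"], kind="stable")
        .reset_index(drop=True)
    )
    out["p_no"] = out["n_no"] / out["n_trials"]
    out.insert(0, "scheme", scheme)
    out.insert(0, "participant_id", pid)
    missing = expected - set(out["x"])
    if missing:
        logger.info(
            "participant %s has empty %s categories at x=%s", pid, scheme, sorted(missing)
        )
    return out


def condition_tables(trials: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Stacked :func:`condition_table` over every participant."""
    parts = [
        condition_table(sub, scheme)
        for _, sub in trials.groupby("participant_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def exclude_participants(
    trials: pd.DataFrame,
    threshold: float = 0.5,
    strict: bool = False,
) -> Tuple[List[str], pd.DataFrame]:
    """Apply the at-or-worse-than-chance exclusion rule.

    A participant is excluded when their proportion of No responses on the
    N probes maximally distant from the mean (the easiest rejections in the
    design) does not exceed ``threshold`` (default 0.5, i.e. chance).  With
    ``strict=True`` only values strictly below the threshold exclude, so a
    participant exactly at chance is retained.

    The maximal distance is each participant's own largest observed
    distance-from-mean among N trials, which is design-dependent (boundary
    old pairs reach x=5, interior ones do not).

    Returns ``(retained_ids, exclusion_log)``; the log has one row per
    participant with the statistic, the trial count, and the decision.
    """
    df = _drop_practice(trials)
    rows = []
    retained: List[str] = []
    for pid, sub in df.groupby("participant_id", sort=True):
        n_probes = sub.loc[sub["relevant_probe_class"] == "N"]
        if n_probes.empty:
            raise ValueError(f"participant {pid} has no N trials")
        max_d = int(n_probes["relevant_dist_from_mean"].max())
        far = n_probes.loc[n_probes["relevant_dist_from_mean"] == max_d]
        p_no = float((far["response"] == "No").mean())
        excluded = p_no < threshold if strict else p_no <= threshold
        rows.append(
            {
                "participant_id": str(pid),
                "max_dist_from_mean": max_d,
                "n_trials": len(far),
                "p_no": p_no,
                "excluded": excluded,
            }
        )
        if not excluded:
            retained.append(str(pid))
        else:
            logger.info(
                "excluding participant %s: p(No)=%.3f at max distance %d", pid, p_no, max_d
            )
    return retained, pd.DataFrame(rows)


@dataclass
class SimilarityPrediction:
    """Observed vs similarity-predicted p(No|M) for one participant."""

    participant_id: str
    p_no_n1a: float
    p_no_n1b: float
    p_no_m_pred: float
    p_no_m_obs: float
    n_n1a: int
    n_n1b: int
    n_m: int
    policy: str

    @property
    def p_yes_m_pred(self) -> float:
        """The p(Yes) form of the same prediction (exact complement)."""
        ya, yb = 1.0 - self.p_no_n1a, 1.0 - self.p_no_n1b
        return ya + yb - ya * yb


def similarity_prediction(
    trials: pd.DataFrame,
    n1_policy: str = "side",
    n_min: int = 5,
) -> SimilarityPrediction:
    """Similarity point prediction for one participant.

    With ``n1_policy="side"`` the two factors of the product are estimated
    from below-range and above-range N1 trials separately, provided both
    sides have at least ``n_min`` trials; otherwise (or with
    ``n1_policy="pooled"``) the pooled N1 proportion enters both factors.
    """
    if n1_policy not in ("side", "pooled"):
        raise ValueError(f"unknown N1 policy: {n1_policy!r}")
    df = _drop_practice(trials)
    pid = str(df["participant_id"].iloc[0])
    n1 = df.loc[
        (df["relevant_probe_class"] == "N") & (df["relevant_dist_from_old"] == 1)
    ]
    if n1.empty:
        raise ValueError(f"participant {pid} has no N1 trials")
    m = df.loc[df["relevant_probe_class"] == "M"]
    below = n1.loc[n1["relevant_side"] == "below"]
    above = n1.loc[n1["relevant_side"] == "above"]

    use_sides = n1_policy == "side" and len(below) >= n_min and len(above) >= n_min
    if use_sides:
        p_a = float((below["response"] == "No").mean())
        p_b = float((above["response"] == "No").mean())
        n_a, n_b = len(below), len(above)
        policy = "side"
    else:
        pooled = float((n1["response"] == "No").mean())
        p_a = p_b = pooled
        n_a, n_b = len(n1), len(n1)
        policy = "pooled"

    return SimilarityPrediction(
        participant_id=pid,
        p_no_n1a=p_a,
        p_no_n1b=p_b,
        p_no_m_pred=p_a * p_b,
        p_no_m_obs=float((m["response"] == "No").mean()) if len(m) else float("nan"),
        n_n1a=n_a,
        n_n1b=n_b,
        n_m=len(m),
        policy=policy,
    )


def similarity_predictions(
    trials: pd.DataFrame, n1_policy: str = "side", n_min: int = 5
) -> pd.DataFrame:
    """Tidy frame of :func:`similarity_prediction` over participants."""
    rows = []
    for _, sub in trials.groupby("participant_id", sort=True):
        pred = similarity_prediction(sub, n1_policy=n1_policy, n_min=n_min)
        row = pred.__dict__.copy()
        row["p_yes_m_pred"] = pred.p_yes_m_pred
        rows.append(row)
    return pd.DataFrame(rows)


def probe_type_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant p(No) for the M, Old and N1 probe conditions.

    The three conditions compared by the one-way repeated-measures ANOVA;
    N1 means N probes one step from the nearest old item.
    """
    df = _drop_practice(trials)
    rows = []
    for pid, sub in df.groupby("participant_id", sort=True):
        no = sub["response"] == "No"
        is_n1 = (sub["relevant_probe_class"] == "N") & (sub["relevant_dist_from_old"] == 1)
        rows.append(
            {
                "participant_id": str(pid),
                "M": float(no[sub["relevant_probe_class"] == "M"].mean()),
                "Old": float(no[sub["relevant_probe_class"] == "O"].mean()),
                "N1": float(no[is_n1].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("participant_id")


def factorial_cell_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant p(No) in the 3x3 (relevant x irrelevant) design.

    Restricts N probes to N1 (one step from the nearest old item) on both
    dimensions, so each factor has levels M, Old, N1.  Returns a tidy frame
    ``participant_id, relevant, irrelevant, n_trials, p_no``; cells with no
    trials are absent.
    """
    df = _drop_practice(trials)
    if df["irrelevant_probe_class"].isna().any():
        raise ValueError("factorial table requires two-dimension (Exp 3-4) trials")

    def level(cls: pd.Series, d_old: pd.Series) -> pd.Series:
        out = cls.map({"M": "M", "O": "Old"})
        out = out.where(cls != "N", "N" + d_old.astype(int).astype(str))
        return out

    work = df.assign(
        relevant=level(df["relevant_probe_class"], df["relevant_dist_from_old"]),
        irrelevant=level(df["irrelevant_probe_class"], df["irrelevant_dist_from_old"]),
        no=(df["response"] == "No").astype(int),
    )
    keep = {"M", "Old", "N1"}
    work = work.loc[work["relevant"].isin(keep) & work["irrelevant"].isin(keep)]
    out = (
        work.groupby(["participant_id", "relevant", "irrelevant"], as_index=False)
        .agg(n_trials=("no", "size"), p_no=("no", "mean"))
    )
    return out
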