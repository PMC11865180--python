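"""Canonical trial-table I/O, source adaptation, and validation.

The canonical schema is one flat CSV row per trial (RFC-4180, UTF-8).
Foreign files (e.g. a deposited raw-data repository with its own column
names and response codings) are adapted through a user-editable
:class:`ColumnMapping` loaded from YAML or JSON, rather than hard-coding
any particular source layout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .types import ResponseRecord

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS: List[str] = [
    "participant_id",
    "experiment",
    "block",
    "trial_index",
    "practice_flag",
    "relevant_dimension",
    "relevant_probe_class",
    "relevant_dist_from_mean",
    "relevant_dist_from_old",
    "relevant_side",
    "irrelevant_probe_class",
    "irrelevant_dist_from_mean",
    "irrelevant_dist_from_old",
    "family",
    "response",
]

#: Columns that must be present and non-null in every row.
REQUIRED_COLUMNS = [
    c for c in CANONICAL_COLUMNS
    if not c.startswith("irrelevant_")
]

MAX_TRIALS_PER_SESSION = 480


@dataclass
class ColumnMapping:
    """Adapter from a foreign file layout to the canonical schema.

    ``columns`` renames source columns to canonical names; ``values``
    recodes cell values per canonical column (e.g. ``{"response": {"1":
    "Yes", "0": "No"}}``).  Recodes must cover every observed code.
    """

    columns: Dict[str, str] = field(default_factory=dict)
    values: Dict[str, Dict[str, str]] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "ColumnMapping":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(columns=data.get("columns", {}), values=data.get("values", {}))

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.rename(columns=self.columns)
        for col, codes in self.values.items():
            if col not in out.columns:
                raise ValueError(f"value mapping targets missing column {col!r}")
            mapped = out[col].astype(str).map(codes)
            unknown = out[col].astype(str)[mapped.isna() & out[col].notna()].unique()
            if len(unknown):
                raise ValueError(
                    f"unmappable codes in column {col!r}: {sorted(unknown)[:10]}"
                )
            out[col] = mapped
        return out


def records_to_table(records: Iterable[ResponseRecord]) -> pd.DataFrame:
    """Flatten :class:`ResponseRecord` objects into the canonical table."""
    rows = []
    for rec in records:
        t = rec.trial
        irr = t.irrelevant_probe
        rows.append(
            {
                "participant_id": rec.participant_id,
                "experiment": t.experiment,
                "block": t.block,
                "trial_index": t.trial_index,
                "practice_flag": t.practice,
                "relevant_dimension": t.relevant_dimension,
                "relevant_probe_class": t.relevant_probe.probe_class,
                "relevant_dist_from_mean": t.relevant_probe.dist_from_mean,
                "relevant_dist_from_old": t.relevant_probe.dist_from_nearest_old,
                "relevant_side": t.relevant_probe.side,
                "irrelevant_probe_class": irr.probe_class if irr else None,
                "irrelevant_dist_from_mean": irr.dist_from_mean if irr else None,
                "irrelevant_dist_from_old": irr.dist_from_nearest_old if irr else None,
                "family": t.relevant_series.family,
                "response": rec.response,
            }
        )
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def _probe_rows_invalid(cls: pd.Series, d_mean: pd.Series, d_old: pd.Series) -> pd.Series:
    d_mean = pd.to_numeric(d_mean, errors="coerce")
    d_old = pd.to_numeric(d_old, errors="coerce")
    bad_class = ~cls.isin(["M", "O", "N"])
    bad_m = (cls == "M") & ((d_mean != 0) | (d_old != 1))
    bad_o = (cls == "O") & ((d_mean != 1) | (d_old != 0))
    bad_n = (cls == "N") & (~d_old.isin([1, 2, 3, 4]) | (d_mean != d_old + 1))
    return bad_class | bad_m | bad_o | bad_n


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical table; raises with row numbers on failure.

    Checks: required columns present; responses are Yes/No; probe-class /
    distance consistency on both dimensions; no more than 480 non-practice
    trials per (participant, experiment).  Returns the validated frame with
    canonical column order and dtypes.
    """
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = df[CANONICAL_COLUMNS].copy()

    bad = pd.Series(False, index=df.index)
    reasons: Dict[int, str] = {}

    def flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        for idx in df.index[mask & ~bad]:
            reasons[idx] = reason
        bad |= mask

    flag(~df["response"].isin(["Yes", "No"]), "response must be Yes or No")
    flag(
        _probe_rows_invalid(
            df["relevant_probe_class"],
            df["relevant_dist_from_mean"],
            df["relevant_dist_from_old"],
        ),
        "inconsistent relevant probe classification",
    )
    has_irr = df["irrelevant_probe_class"].notna()
    flag(
        has_irr
        & _probe_rows_invalid(
            df["irrelevant_probe_class"].where(has_irr, "M"),
            df["irrelevant_dist_from_mean"].where(has_irr, 0),
            df["irrelevant_dist_from_old"].where(has_irr, 1),
        ),
        "inconsistent irrelevant probe classification",
    )
    if bad.any():
        lines = [
            f"  row {idx}: {reasons[idx]}" for idx in list(df.index[bad])[:20]
        ]
        raise ValueError(
            f"{int(bad.sum())} invalid rows:\n" + "\n".join(lines)
        )

    counts = (
        df.loc[~df["practice_flag"].astype(bool)]
        .groupby(["participant_id", "experiment"])
        .size()
    )
    over = counts[counts > MAX_TRIALS_PER_SESSION]
    if len(over):
        raise ValueError(
            f"sessions exceed {MAX_TRIALS_PER_SESSION} non-practice trials: "
            f"{over.to_dict()}"
        )
    for col in ("relevant_dist_from_mean", "relevant_dist_from_old"):
        df[col] = df[col].astype(int)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a validated canonical table as CSV (lossless round-trip)."""
    validate_table(df).to_csv(path, index=False)


def read_trials(path, mapping: Optional[ColumnMapping] = None) -> pd.DataFrame:
    """Read a trial table, adapting a foreign layout if a mapping is given.

    Rows with a missing response are dropped with a logged count; remaining
    rows must pass :func:`validate_table` (failures are reported with row
    numbers).
    """
    # "n/a" is the canonical side code for M/O probes, not a missing value
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    if mapping is not None:
        df = mapping.apply(df)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if df["response"].isna().any():
        n = int(df["response"].isna().sum())
        logger.warning("%s: dropping %d rows with no response", path, n)
        df = df.loc[df["response"].notna()]
    if df.empty:
        return df[CANONICAL_COLUMNS]
    return validate_table(df)
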