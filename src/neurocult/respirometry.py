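"""Mitochondrial respiration state summaries and derived ratios.

Input tables carry one row per replicate with oxygen-consumption rates for
the V4 state under glutamate/malate (``V4_gm``), the ADP-stimulated V3
state (``V3``), and the V4 state after succinate (``V4_succ``), in
pmol/s per mg protein (units are carried as opaque labels, never
converted).  The respiratory control index (RCI) is V3 / V4 with the
glutamate/malate V4 in the denominator, computed per replicate before any
averaging.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATE_COLUMNS",
    "respiratory_control_index",
    "percent_change",
    "fold_decrease",
    "group_respiration_summary",
]

STATE_COLUMNS = ("V4_gm", "V3", "V4_succ")


def respiratory_control_index(v3, v4):
    """Respiratory control index V3 / V4 (coupling of the chain).

    Accepts scalars or arrays; every V4 must be positive.
    """
    v3 = np.asarray(v3, dtype=float)
    v4 = np.asarray(v4, dtype=float)
    if np.any(v4 <= 0):
        raise ValueError("V4 must be > 0")
    rci = v3 / v4
    return float(rci) if rci.ndim == 0 else rci


def percent_change(reference: float, treated: float) -> float:
    """Percent change relative to ``reference``: 100 (ref - treated) / ref.

    Positive for a reduction.  ``reference`` must be positive.
    """
    if not reference > 0:
        raise ValueError("reference must be > 0")
    return 100.0 * (reference - treated) / reference


def fold_decrease(reference: float, treated: float) -> float:
    """Fold decrease ``reference / treated`` (e.g. RCI sham vs hypoxia)."""
    if not treated > 0:
        raise ValueError("treated must be > 0")
    return reference / treated


def group_respiration_summary(
    table: pd.DataFrame, expected_groups: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-group mean +/- SEM for each respiration state and the RCI.

    The RCI (V3 / V4_gm) is computed per replicate and then averaged, so
    groups report a mean of ratios with its own SEM.  SEM is NaN for
    single-replicate groups.  With ``expected_groups``, any group absent
    from the table raises an error naming it.
    """
    missing_cols = [c for c in ("group", *STATE_COLUMNS) if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns: {missing_cols}")
    if expected_groups is not None:
        present = set(table["group"])
        for g in expected_groups:
            if g not in present:
                raise ValueError(f"group {g!r} has no replicates")
    if table.empty:
        raise ValueError("table has no replicates")
    work = table.copy()
    work["RCI"] = respiratory_control_index(
        work["V3"].to_numpy(), work["V4_gm"].to_numpy()
    )
    rows = []
    for group, sub in work.groupby("group", sort=False):
        row: dict[str, object] = {"group": group, "n": len(sub)}
        for col in (*STATE_COLUMNS, "RCI"):
            values = sub[col].to_numpy(dtype=float)
            row[f"{col}_mean"] = values.mean()
            row[f"{col}_sem"] = (
                values.std(ddof=1) / np.sqrt(len(values))
                if len(values) > 1
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
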