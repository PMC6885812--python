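"""Relative gene expression by the ddCt method.

Per sample, the target-gene cycle threshold is normalized to a reference
(housekeeping) gene, ``dCt = Ct_target - Ct_reference``; per group, the
calibrator group's mean dCt is subtracted, ``ddCt = dCt - mean dCt(cal)``,
and the fold change is ``2**(-ddCt)`` (amplification efficiency fixed at
2, no efficiency correction).  Technical replicates (same sample and gene)
are averaged at the Ct level.  Group folds are the arithmetic mean of
per-sample folds with SEM, matching mean-plus-SEM bar-plot reporting; a
geometric mean is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["delta_ct", "fold_change"]

_CT_SOFT_RANGE = (10.0, 40.0)


def delta_ct(records: pd.DataFrame, reference_gene: str = "Oaz1") -> pd.DataFrame:
    """Per-sample dCt of every target gene against the reference gene.

    ``records`` needs columns sample, group, gene, Ct.  Technical
    replicates are averaged first.  Ct values outside 10-40 trigger a
    warning (soft validation only).

    Returns a frame with columns sample, group, gene, delta_ct (reference
    gene rows are consumed, not emitted).

    Raises
    ------
    ValueError
        If a sample lacks the reference gene (the sample is named).
    """
    required = {"sample", "group", "gene", "Ct"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    ct = records["Ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("Ct values must be finite")
    lo, hi = _CT_SOFT_RANGE
    if np.any((ct < lo) | (ct > hi)):
        warnings.warn(
            f"Ct values outside the typical {lo}-{hi} cycle range",
            stacklevel=2,
        )
    # technical replicates: mean Ct per sample/gene
    mean_ct = (
        records.groupby(["sample", "group", "gene"], sort=False)["Ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (sample, group), sub in mean_ct.groupby(["sample", "group"], sort=False):
        ref_rows = sub[sub["gene"] == reference_gene]
        if ref_rows.empty:
            raise ValueError(
                f"sample {sample!r} lacks reference gene {reference_gene!r}"
            )
        ref_ct = float(ref_rows["Ct"].iloc[0])
        for row in sub[sub["gene"] != reference_gene].itertuples(index=False):
            rows.append(
                {
                    "sample": sample,
                    "group": group,
                    "gene": row.gene,
                    "delta_ct": float(row.Ct) - ref_ct,
                }
            )
    if not rows:
        raise ValueError("no target genes found")
    return pd.DataFrame(rows)


def fold_change(
    delta_ct_table: pd.DataFrame,
    calibrator_group: str,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Per-group fold change ``2**(-ddCt)`` against a calibrator group.

    ddCt subtracts the calibrator group's *mean* dCt (per gene); folds are
    computed per sample and then averaged per group (``mean="arithmetic"``
    with SEM, or ``"geometric"``).  By construction the calibrator's mean
    ddCt is 0, so its geometric-mean fold is exactly 1.

    Returns columns group, gene, fold, sem, n.
    """
    required = {"sample", "group", "gene", "delta_ct"}
    if not required.issubset(delta_ct_table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    cal = delta_ct_table[delta_ct_table["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    cal_means = cal.groupby("gene")["delta_ct"].mean()
    rows = []
    for (group, gene), sub in delta_ct_table.groupby(["group", "gene"], sort=False):
        if gene not in cal_means.index:
            raise ValueError(f"calibrator lacks gene {gene!r}")
        ddct = sub["delta_ct"].to_numpy(dtype=float) - cal_means[gene]
        folds = np.exp2(-ddct)
        n = folds.size
        if mean == "arithmetic":
            center = folds.mean()
        else:
            center = float(np.exp2(np.log2(folds).mean()))
        sem = folds.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
        rows.append(
            {"group": group, "gene": gene, "fold": center, "sem": sem, "n": n}
        )
    return pd.DataFrame(rows)
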