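"""Endoreduplication index (EI) from flow-cytometry ploidy classes.

EI weights the percentage of nuclei in each ploidy class by the number of
endocycles needed to reach it:

    EI = 0*(%2C) + 1*(%4C) + 2*(%8C) + 3*(%16C) + 4*(%32C), on fractions,

so EI is the mean number of endocycles per nucleus and lies in [0, 4].
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

PLOIDY_CLASSES = ("2C", "4C", "8C", "16C", "32C")
EI_WEIGHTS = np.arange(len(PLOIDY_CLASSES), dtype=float)  # 0..4
SUM_TOLERANCE = 0.5  # percent, allows for rounding in input tables


def endoreduplication_index(percentages: Sequence[float]) -> float:
    """EI of one distribution given as percentages over 2C..32C."""
    p = np.asarray(percentages, dtype=float)
    if p.shape != (len(PLOIDY_CLASSES),):
        raise ValueError(f"expected {len(PLOIDY_CLASSES)} class percentages")
    if (p < 0).any():
        raise ValueError("percentages must be >= 0")
    if abs(p.sum() - 100.0) > SUM_TOLERANCE:
        raise ValueError(f"percentages sum to {p.sum():.3f}, not 100 +/- {SUM_TOLERANCE}")
    return float(np.dot(EI_WEIGHTS, p / 100.0))


def ei_table(distributions: pd.DataFrame) -> pd.DataFrame:
    """Append an EI column to a table with pct_2C..pct_32C columns."""
    cols = [f"pct_{c}" for c in PLOIDY_CLASSES]
    missing = [c for c in cols if c not in distributions.columns]
    if missing:
        raise ValueError(f"missing ploidy columns: {missing}")
    out = distributions.copy()
    out["EI"] = [
        endoreduplication_index(row) for row in out[cols].to_numpy(dtype=float)
    ]
    return out


def summarize_ei(table: pd.DataFrame, group_col: str = "condition",
                 compare: Optional[Tuple[str, str]] = None) -> Dict[str, object]:
    """Mean +/- SEM of EI per group and an optional Welch t-test.

    SEM = sd / sqrt(n) and is reported as missing for single-replicate
    groups. The comparison, when requested, is a two-sided Welch t-test
    on the replicate EIs of the two named groups.
    """
    if "EI" not in table.columns:
        table = ei_table(table)
    summary_rows = []
    for grp, sub in table.groupby(group_col):
        ei = sub["EI"].to_numpy(dtype=float)
        sem = float(ei.std(ddof=1) / np.sqrt(len(ei))) if len(ei) >= 2 else np.nan
        summary_rows.append({group_col: grp, "n": len(ei),
                             "mean_EI": float(ei.mean()), "sem_EI": sem})
    result: Dict[str, object] = {"summary": pd.DataFrame(summary_rows)}
    if compare is not None:
        a, b = compare
        ei_a = table.loc[table[group_col] == a, "EI"].to_numpy(dtype=float)
        ei_b = table.loc[table[group_col] == b, "EI"].to_numpy(dtype=float)
        if len(ei_a) < 2 or len(ei_b) < 2:
            raise ValueError("Welch test needs >= 2 replicates per group")
        if np.allclose(ei_a, ei_a[0]) and np.allclose(ei_b, ei_b[0]) \
                and np.isclose(ei_a[0], ei_b[0]):
            stat, p, df = 0.0, 1.0, float(len(ei_a) + len(ei_b) - 2)
        else:
            res = stats.ttest_ind(ei_a, ei_b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        result["welch"] = {"groups": (a, b), "t": stat, "p": p, "df": df}
    return result
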