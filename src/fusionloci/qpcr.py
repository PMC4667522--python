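"""RT-qPCR quantification: delta-delta-Ct fold changes and arrow calls.

Fold change between a treated and a mock condition is 2^-ddCt where
ddCt = (Ct_target - Ct_housekeeping)_treated - (Ct_target - Ct_housekeeping)_mock,
with replicate Ct values averaged per condition before differencing.  Calls
follow the two-fold convention: up when fold >= threshold, down when
fold <= 1/threshold (boundaries inclusive: "at least two-fold"), no change
otherwise, and not-expressed when no amplification was recorded.  Across a
tumour panel, the majority rule calls a direction when at least k of n
samples individually pass the two-fold bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChange",
    "RegulationCall",
    "delta_delta_ct",
    "ddct_table",
    "classify_regulation",
    "tumor_majority_call",
    "ttest_delta_ct",
]

DEFAULT_HOUSEKEEPING = "18S"


@dataclass(frozen=True)
class FoldChange:
    target: str
    fold: float
    ddct: float
    se_ddct: float
    n_treated: int
    n_mock: int


@dataclass(frozen=True)
class RegulationCall:
    fold: float | None
    arrow: str  # up | down | none | not_expressed
    threshold: float


def _delta_ct(df: pd.DataFrame, target: str, condition: str,
              housekeeping: str, ct_ceiling: float | None) -> np.ndarray:
    """Per-replicate housekeeping-normalized Ct values for one condition."""
    sel = df[df["condition"] == condition]
    hk = sel[sel["target"] == housekeeping].set_index("replicate")["ct"]
    if hk.empty:
        raise ValueError(
            f"no housekeeping ({housekeeping!r}) measurement for condition {condition!r}"
        )
    tgt = sel[sel["target"] == target].set_index("replicate")["ct"]
    if ct_ceiling is not None:
        tgt = tgt[tgt <= ct_ceiling]
    if tgt.empty:
        return np.array([])
    common = tgt.index.intersection(hk.index)
    if len(common):
        return (tgt.loc[common] - hk.loc[common]).to_numpy(dtype=float)
    # Unpaired replicates: normalize against the mean housekeeping Ct.
    return (tgt - hk.mean()).to_numpy(dtype=float)


def delta_delta_ct(ct: pd.DataFrame, target: str, treated: str, mock: str,
                   housekeeping: str = DEFAULT_HOUSEKEEPING,
                   ct_ceiling: float | None = None) -> FoldChange | None:
    """Fold change of one target between two conditions (2^-ddCt).

    Returns None when the target shows no amplification in either condition
    (absent rows, or all Ct above ``ct_ceiling``), which downstream maps to a
    not-expressed call.
    """
    d_treated = _delta_ct(ct, target, treated, housekeeping, ct_ceiling)
    d_mock = _delta_ct(ct, target, mock, housekeeping, ct_ceiling)
    if d_treated.size == 0 or d_mock.size == 0:
        return None
    ddct = float(d_treated.mean() - d_mock.mean())
    se = float(math.sqrt(
        (d_treated.std(ddof=1) ** 2 / d_treated.size if d_treated.size > 1 else 0.0)
        + (d_mock.std(ddof=1) ** 2 / d_mock.size if d_mock.size > 1 else 0.0)
    ))
    return FoldChange(target, 2.0 ** (-ddct), ddct, se,
                      int(d_treated.size), int(d_mock.size))


def ddct_table(ct: pd.DataFrame, treated: str, mock: str,
               housekeeping: str = DEFAULT_HOUSEKEEPING,
               ct_ceiling: float | None = None,
               threshold: float = 2.0) -> pd.DataFrame:
    """Fold change, call and t-test p-value for every non-housekeeping target."""
    rows = []
    for target in sorted(ct["target"].unique()):
        if target == housekeeping:
            continue
        fc = delta_delta_ct(ct, target, treated, mock, housekeeping, ct_ceiling)
        if fc is None:
            rows.append({"target": target, "fold": float("nan"),
                         "ddct": float("nan"), "se_ddct": float("nan"),
                         "arrow": "not_expressed", "p_value": float("nan")})
            continue
        call = classify_regulation(fc.fold, threshold)
        p = ttest_delta_ct(ct, target, treated, mock, housekeeping, ct_ceiling)
        rows.append({"target": target, "fold": fc.fold, "ddct": fc.ddct,
                     "se_ddct": fc.se_ddct, "arrow": call.arrow, "p_value": p})
    return pd.DataFrame(rows, columns=["target", "fold", "ddct", "se_ddct",
                                       "arrow", "p_value"])


def classify_regulation(fold: float | None, threshold: float = 2.0) -> RegulationCall:
    """Two-fold arrow call: up / down / none / not_expressed."""
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    if fold is None or (isinstance(fold, float) and math.isnan(fold)):
        return RegulationCall(None, "not_expressed", threshold)
    if fold <= 0:
        raise ValueError("fold change must be positive")
    if fold >= threshold:
        return RegulationCall(fold, "up", threshold)
    if fold <= 1.0 / threshold:
        return RegulationCall(fold, "down", threshold)
    return RegulationCall(fold, "none", threshold)


def tumor_majority_call(folds: Sequence[float], k: int = 4, n: int = 7,
                        threshold: float = 2.0,
                        allow_missing: bool = False) -> RegulationCall:
    """Majority rule over a tumour panel: direction called when >= k of n
    samples individually change at least ``threshold``-fold.

    The representative fold reported is the geometric mean of the per-sample
    folds.
    """
    folds = [f for f in folds if f is not None and not math.isnan(f)]
    if len(folds) < n and not allow_missing:
        raise ValueError(f"expected {n} per-sample folds, got {len(folds)}")
    if not folds:
        return RegulationCall(None, "not_expressed", threshold)
    n_up = sum(1 for f in folds if f >= threshold)
    n_down = sum(1 for f in folds if f <= 1.0 / threshold)
    geo = float(np.exp(np.mean(np.log(folds))))
    if n_up >= k:
        return RegulationCall(geo, "up", threshold)
    if n_down >= k:
        return RegulationCall(geo, "down", threshold)
    return RegulationCall(geo, "none", threshold)


def ttest_delta_ct(ct: pd.DataFrame, target: str, treated: str, mock: str,
                   housekeeping: str = DEFAULT_HOUSEKEEPING,
                   ct_ceiling: float | None = None) -> float:
    """Two-sample Student's t-test between mock and treated delta-Ct replicates."""
    a = _delta_ct(ct, target, treated, housekeeping, ct_ceiling)
    b = _delta_ct(ct, target, mock, housekeeping, ct_ceiling)
    if a.size < 2 or b.size < 2:
        return float("nan")
    return float(stats.ttest_ind(a, b).pvalue)
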