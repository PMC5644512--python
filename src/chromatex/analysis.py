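"""Cohort-level feature statistics: normalization, correlation screen,
one-way ANOVA across the seven classes, and the reactive-vs-neoplastic
Welch t-test.

The correlation screen reports feature pairs in two bands of the absolute
Pearson coefficient (|rho| >= 0.95 and 0.90 <= |rho| < 0.95), the bands
used to flag redundant features before model building.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import feature_columns

__all__ = [
    "CorrelationReport",
    "normalize_features",
    "correlation_screen",
    "anova_by_class",
    "reactive_vs_neoplastic_test",
    "REACTIVE_CLASSES",
    "NEOPLASTIC_CLASSES",
]

REACTIVE_CLASSES: tuple[str, ...] = ("MET", "REG")
NEOPLASTIC_CLASSES: tuple[str, ...] = ("LSIL", "HSIL", "CIS", "SCC")


@dataclass
class CorrelationReport:
    """Pearson correlation matrix plus the high-correlation pair list."""

    rho: pd.DataFrame
    high_pairs: list[tuple[str, str, float, str]]  # (fi, fj, |rho|, band)


def normalize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature column to [0, 1] (labels untouched).

    Constant columns are mapped to 0.5 with a warning.  Idempotent.
    """
    out = table.copy()
    for col in feature_columns(table):
        v = out[col].to_numpy(dtype=np.float64)
        lo, hi = v.min(), v.max()
        if hi == lo:
            warnings.warn(f"constant feature column {col}; normalized to 0.5")
            out[col] = 0.5
        else:
            out[col] = (v - lo) / (hi - lo)
    return out


def correlation_screen(table: pd.DataFrame) -> CorrelationReport:
    """Pearson correlations between features, with the two printed bands."""
    cols = feature_columns(table)
    if len(table) < 3:
        raise ValueError("correlation screen needs at least 3 rows")
    usable = []
    for col in cols:
        if table[col].nunique() <= 1:
            warnings.warn(f"constant feature column {col} excluded from correlations")
        else:
            usable.append(col)
    X = table[usable].to_numpy(dtype=np.float64)
    rho = pd.DataFrame(np.corrcoef(X, rowvar=False), index=usable, columns=usable)
    pairs: list[tuple[str, str, float, str]] = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            r = abs(float(rho.iat[a, b]))
            if r >= 0.95:
                band = ">=0.95"
            elif r >= 0.90:
                band = "0.90-0.95"
            else:
                continue
            pairs.append((usable[a], usable[b], r, band))
    return CorrelationReport(rho=rho, high_pairs=pairs)


def anova_by_class(table: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each feature across the class labels."""
    if "label" not in table.columns:
        raise ValueError("table has no label column")
    groups = {lab: sub for lab, sub in table.groupby("label")}
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two classes")
    if any(len(sub) < 2 for sub in groups.values()):
        raise ValueError("every class needs at least two rows")
    rows = []
    for col in feature_columns(table):
        samples = [sub[col].to_numpy(dtype=np.float64) for sub in groups.values()]
        F, p = stats.f_oneway(*samples)
        rows.append({"feature": col, "F": float(F), "p": float(p),
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def reactive_vs_neoplastic_test(
    table: pd.DataFrame,
    reactive: tuple[str, ...] = REACTIVE_CLASSES,
    neoplastic: tuple[str, ...] = NEOPLASTIC_CLASSES,
) -> pd.DataFrame:
    """Two-sided Welch t-test of each feature, reactive vs neoplastic atypia.

    Star levels: ``*`` at p < 0.05, ``**`` at p < 0.01.
    """
    if "label" not in table.columns:
        raise ValueError("table has no label column")
    a = table[table["label"].isin(reactive)]
    b = table[table["label"].isin(neoplastic)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both pooled groups need at least two rows")
    rows = []
    for col in feature_columns(table):
        t, p = stats.ttest_ind(
            a[col].to_numpy(dtype=np.float64),
            b[col].to_numpy(dtype=np.float64),
            equal_var=False,
        )
        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append({"feature": col, "t": float(t), "p": float(p), "stars": stars})
    return pd.DataFrame(rows)
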