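"""Cohort table schema, loading and derived columns.

One row per subject: demographics (age, sex, education, BMI,
hypertension), Fazekas periventricular/deep scores and the WMH severity
group they define, lesion volumes, choroid-plexus (ChP) volumetrics,
glymphatic indices (ALPS, BOLD-CSF coupling, DCE parameters) and the
MMSE/MoCA cognitive scores.

Grouping rule: the periventricular and deep Fazekas scores (each 0-3)
are summed; total 0 -> healthy control (HC), 1-3 -> mild WMH,
4-6 -> severe WMH.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("HC", "mild", "severe")

#: columns validated when present: (name, min, max)
_RANGE_CHECKS = (
    ("fazekas_pwmh", 0, 3),
    ("fazekas_dwmh", 0, 3),
    ("fazekas_total", 0, 6),
    ("mmse", 0, 30),
    ("moca", 0, 30),
)

_NONNEG = (
    "pwmh_volume",
    "dwmh_volume",
    "total_wmh_volume",
    "icv",
    "chp_volume",
    "latvent_volume",
)


def group_from_fazekas_total(total) -> pd.Series | str:
    """Map summed Fazekas score to WMH severity group (pure function)."""
    def one(t):
        if not 0 <= t <= 6:
            raise ValueError(f"fazekas_total {t} outside 0-6")
        if t == 0:
            return "HC"
        return "mild" if t <= 3 else "severe"

    if np.isscalar(total):
        return one(total)
    return pd.Series([one(t) for t in total], index=getattr(total, "index", None))


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Fill derived columns when absent (group, totals, BMI, ChP ratios).

    Missing inputs propagate as missing values, never as zeros.
    """
    df = df.copy()
    if "fazekas_total" not in df and {"fazekas_pwmh", "fazekas_dwmh"} <= set(df):
        df["fazekas_total"] = df["fazekas_pwmh"] + df["fazekas_dwmh"]
    if "group" not in df and "fazekas_total" in df:
        df["group"] = group_from_fazekas_total(df["fazekas_total"])
    if "bmi" not in df and {"weight", "height"} <= set(df):
        df["bmi"] = df["weight"] / df["height"] ** 2
    if "total_wmh_volume" not in df and {"pwmh_volume", "dwmh_volume"} <= set(df):
        df["total_wmh_volume"] = df["pwmh_volume"] + df["dwmh_volume"]
    if "chp_latvent" not in df and {"chp_volume", "latvent_volume"} <= set(df):
        df["chp_latvent"] = df["chp_volume"] / df["latvent_volume"]
    if "chp_icv" not in df and {"chp_volume", "icv"} <= set(df):
        df["chp_icv"] = df["chp_volume"] / df["icv"]
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate ranges, consistency and subject uniqueness; return df."""
    if "subject_id" in df and df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id: {dupes}")
    for col, lo, hi in _RANGE_CHECKS:
        if col in df:
            vals = df[col].dropna()
            bad = vals[(vals < lo) | (vals > hi)]
            if len(bad):
                raise ValueError(f"{col} outside [{lo}, {hi}]: {bad.tolist()}")
    for col in _NONNEG:
        if col in df:
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValueError(f"{col} contains negative volumes")
    if {"fazekas_pwmh", "fazekas_dwmh", "fazekas_total"} <= set(df):
        rows = df.dropna(subset=["fazekas_pwmh", "fazekas_dwmh", "fazekas_total"])
        mismatch = rows["fazekas_total"] != rows["fazekas_pwmh"] + rows["fazekas_dwmh"]
        if mismatch.any():
            raise ValueError("fazekas_total != fazekas_pwmh + fazekas_dwmh")
    if "sex" in df:
        vals = set(df["sex"].dropna().unique())
        if not vals <= {"M", "F"}:
            raise ValueError(f"sex must be M/F, got {vals}")
    return df


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load a cohort CSV (UTF-8, '.' decimal, empty cells = missing).

    Derived columns (fazekas_total, group, bmi, total_wmh_volume,
    chp_latvent, chp_icv) are filled when absent; row count preserved.
    """
    df = pd.read_csv(path)
    n = len(df)
    df = derive_columns(df)
    validate_cohort(df)
    assert len(df) == n
    return df


def save_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
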