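"""Bench-assay quantification: DNA fibre replication rates, ddCt relative
expression, and foci-positive cell fractions.

Fibre rates convert an IdU tract length in pixels to kb/min:
``V = (x * 0.132 um/pixel * 2.59 kb/um) / t``, with the pulse duration
``t`` taken from named presets (normoxia: 20 min IdU; hypoxia: 60 min)
so the two conditions cannot be silently mixed up.

ddCt fold change follows Livak: ``fold = 2**-ddCt`` with
``ddCt = (Ct_target - Ct_ref)_treated - (Ct_target - Ct_ref)_control``;
replicates are aggregated by mean Ct before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UM_PER_PIXEL = 0.132
KB_PER_UM = 2.59

#: IdU pulse durations (minutes) by labelling scheme.
PULSE_PRESETS = {"normoxia": 20.0, "hypoxia": 60.0}


@dataclass(frozen=True)
class FibreTrack:
    track_id: str
    x_pixels: float
    t_minutes: float
    condition: str = ""

    def __post_init__(self):
        if self.x_pixels < 0:
            raise ValueError("track length must be >= 0")
        if self.t_minutes <= 0:
            raise ValueError("pulse duration must be > 0")


@dataclass(frozen=True)
class CtRecord:
    sample: str
    target: str
    ct_target: float
    ct_ref: float
    condition: str
    reference: str = "18S"


def fibre_rate(x_pixels, t_minutes, um_per_pixel: float = UM_PER_PIXEL,
               kb_per_um: float = KB_PER_UM):
    """Replication rate in kb/min for tract length(s) in pixels."""
    x = np.asarray(x_pixels, dtype=float)
    t = np.asarray(t_minutes, dtype=float)
    if np.any(t <= 0):
        raise ValueError("pulse duration must be > 0")
    if np.any(x < 0):
        raise ValueError("track length must be >= 0")
    v = (x * um_per_pixel * kb_per_um) / t
    return float(v) if v.ndim == 0 else v


def fibre_rates_table(tracks: pd.DataFrame, condition_col: str = "condition",
                      length_col: str = "x_pixels",
                      pulse_minutes: dict[str, float] | None = None) -> pd.DataFrame:
    """Add a ``rate_kb_per_min`` column, mapping condition to pulse time
    via presets (or an explicit mapping)."""
    presets = pulse_minutes or PULSE_PRESETS
    unknown = set(tracks[condition_col]) - set(presets)
    if unknown:
        raise KeyError(f"no pulse preset for condition(s) {sorted(unknown)}")
    t = tracks[condition_col].map(presets).astype(float)
    out = tracks.copy()
    out["rate_kb_per_min"] = fibre_rate(tracks[length_col].values, t.values)
    return out


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Relative fold change of the treated condition vs control."""
    if treated.target != control.target:
        raise ValueError(
            f"mismatched target genes: {treated.target!r} vs {control.target!r}"
        )
    if treated.reference != control.reference:
        raise ValueError("mismatched reference genes")
    ddct = (treated.ct_target - treated.ct_ref) - (control.ct_target - control.ct_ref)
    return float(2.0 ** (-ddct))


def ddct_table(ct: pd.DataFrame, control_condition: str = "control") -> pd.DataFrame:
    """Fold changes per (target, condition) vs the control condition.

    Expects columns sample, target, ct_target, ct_ref, condition.
    Replicates are aggregated by mean Ct before differencing.
    """
    required = {"target", "ct_target", "ct_ref", "condition"}
    if missing := required - set(ct.columns):
        raise KeyError(f"Ct table missing columns {sorted(missing)}")
    means = ct.groupby(["target", "condition"])[["ct_target", "ct_ref"]].mean()
    rows = []
    for target, sub in means.groupby(level="target"):
        sub = sub.droplevel("target")
        if control_condition not in sub.index:
            raise ValueError(f"control condition {control_condition!r} absent for {target}")
        dct_ctrl = sub.loc[control_condition, "ct_target"] - sub.loc[control_condition, "ct_ref"]
        for condition, row in sub.iterrows():
            ddct = (row["ct_target"] - row["ct_ref"]) - dct_ctrl
            rows.append(
                {"target": target, "condition": condition,
                 "ddct": ddct, "fold_change": 2.0 ** (-ddct)}
            )
    return pd.DataFrame(rows)


def foci_positive_fraction(foci_counts, threshold: int = 5, strict: bool = True) -> float:
    """Percentage of cells with foci count above ``threshold``.

    The default replicates the ">5 foci per nucleus" scoring convention:
    strictly greater, so a cell with exactly 5 foci is negative.
    """
    counts = np.asarray(foci_counts)
    if counts.size == 0:
        raise ValueError("empty foci table")
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("foci counts must be non-negative integers")
    positive = counts > threshold if strict else counts >= threshold
    return float(100.0 * positive.mean())


def foci_table(foci: pd.DataFrame, threshold: int = 5, strict: bool = True,
               count_col: str = "foci_count") -> pd.DataFrame:
    """Foci-positive percentage per (marker, condition)."""
    group_cols = [c for c in ("marker", "condition") if c in foci.columns]
    rows = []
    for key, sub in foci.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(group_cols, key))
            | {"pct_positive": foci_positive_fraction(sub[count_col].values, threshold, strict),
               "n_cells": len(sub)}
        )
    return pd.DataFrame(rows)
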