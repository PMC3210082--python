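"""CCSVI classification and VHISS severity scoring.

Five extra-/trans-cranial Doppler venous-hemodynamic (VH) criteria are
assessed per subject: (1) reflux in the internal jugular and/or vertebral
veins, (2) reflux in the deep cerebral veins, (3) B-mode stenosis of the
internal jugular vein, (4) absent Doppler flow signal in the internal
jugular/vertebral veins, and (5) negative difference in internal-jugular
cross-sectional area. A subject is CCSVI-positive when at least two criteria
are fulfilled (a count, regardless of sub-score weights). The venous
hemodynamic insufficiency severity score is the sum
VHISS = VHISS1 + ... + VHISS5, an ordinal severity measure from 0 to 16.

The per-criterion maxima are a weighting convention defined outside this
package; the shipped default (4, 4, 4, 2, 2) sums to the published bound of
16 and is fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_VHISS_MAXIMA", "VhProfile", "ccsvi_status", "vhiss", "cohort_summary"]

DEFAULT_VHISS_MAXIMA: tuple[int, ...] = (4, 4, 4, 2, 2)
N_CRITERIA = 5
CCSVI_POSITIVE_MIN_CRITERIA = 2


@dataclass
class VhProfile:
    """Five VH criterion sub-scores and fulfilled flags for one subject."""

    subscores: tuple[int, ...]
    fulfilled: tuple[bool, ...]
    maxima: tuple[int, ...] = DEFAULT_VHISS_MAXIMA

    def __post_init__(self) -> None:
        self.subscores = tuple(int(s) for s in self.subscores)
        self.fulfilled = tuple(bool(f) for f in self.fulfilled)
        self.maxima = tuple(int(m) for m in self.maxima)
        if not (len(self.subscores) == len(self.fulfilled) == len(self.maxima) == N_CRITERIA):
            raise ValueError("profile needs exactly five criteria")
        for i, (s, m) in enumerate(zip(self.subscores, self.maxima), start=1):
            if not 0 <= s <= m:
                raise ValueError(f"VHISS{i} = {s} outside [0, {m}]")
        for i, (s, f) in enumerate(zip(self.subscores, self.fulfilled), start=1):
            if f and s < 1:
                raise ValueError(f"criterion {i} fulfilled but sub-score is 0")


def ccsvi_status(profile: VhProfile) -> bool:
    """True iff at least two VH criteria are fulfilled."""
    return sum(profile.fulfilled) >= CCSVI_POSITIVE_MIN_CRITERIA


def vhiss(profile: VhProfile) -> int:
    """VHISS = sum of the five criterion sub-scores (0..16 by construction)."""
    return int(sum(profile.subscores))


def cohort_summary(
    profiles: list[VhProfile], groups: list[str], group_order: list[str] | None = None
) -> pd.DataFrame:
    """Per-group CCSVI prevalence and VHISS mean (SD).

    Returns a table with one row per group: n, n CCSVI-positive, percentage
    positive (1 decimal), VHISS mean and SD.
    """
    if len(profiles) != len(groups):
        raise ValueError("profiles and group labels differ in length")
    if not profiles:
        raise ValueError("empty cohort")
    order = group_order or list(dict.fromkeys(groups))
    unknown = set(groups) - set(order)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    df = pd.DataFrame(
        {
            "group": groups,
            "positive": [ccsvi_status(p) for p in profiles],
            "vhiss": [vhiss(p) for p in profiles],
        }
    )
    rows = []
    for g in order:
        sub = df[df["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} has no profiles")
        n = len(sub)
        npos = int(sub["positive"].sum())
        rows.append(
            {
                "group": g,
                "n": n,
                "n_ccsvi_positive": npos,
                "pct_ccsvi_positive": round(100.0 * npos / n, 1),
                "vhiss_mean": float(sub["vhiss"].mean()),
                "vhiss_sd": float(sub["vhiss"].std(ddof=1)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
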