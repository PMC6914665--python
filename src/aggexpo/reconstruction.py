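"""Reverse dosimetry: absorbed-dose reconstruction from urine voids.

The minimum absorbed dose of a preservative is the total parent-compound
mass recovered in urine over the observation window, normalised to body
weight and the number of product-use days:

    D_min = sum_i(C_i * V_i) / (BW * n_use_days)        [μg/kg-d]

with non-detected concentrations imputed as zero.  Because the urinary
assay misses hydrolysis and oxidative metabolites, D_min bounds the true
absorbed dose from below; dividing by the urinary excretion fraction F_UE
observed after controlled oral dosing gives a (likely conservative) upper
bound D_max = D_min / F_UE.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .study_io import (
    DoseEstimate,
    Participant,
    TableValidationError,
    UseProfile,
    VoidTable,
)

__all__ = [
    "excreted_mass",
    "min_absorbed_dose",
    "max_absorbed_dose",
    "reconstruct_doses",
    "summarize_by_use_group",
]


def excreted_mass(voids: VoidTable, participant_id: str, analyte: str) -> float:
    """Total mass (μg) of an analyte excreted by one participant.

    Sums concentration x volume over all voids; non-detects contribute 0
    (zero-imputation, consistent with a minimum-dose estimate).
    """
    sub = voids.for_participant(participant_id)
    sub = sub[sub["analyte"] == analyte]
    if sub.empty:
        raise KeyError(f"analyte {analyte!r} absent for participant {participant_id!r}")
    conc = np.where(sub["detected"].to_numpy(), sub["conc_ug_L"].to_numpy(), 0.0)
    return float(np.sum(conc * sub["volume_L"].to_numpy()))


def min_absorbed_dose(
    total_mass_ug: float, body_weight_kg: float, n_use_days: float = 4
) -> float:
    """Average daily minimum absorbed dose (μg/kg-d)."""
    if body_weight_kg <= 0:
        raise TableValidationError(f"body weight must be > 0, got {body_weight_kg}")
    if n_use_days <= 0:
        raise TableValidationError(f"n_use_days must be > 0, got {n_use_days}")
    if total_mass_ug < 0:
        raise TableValidationError("excreted mass must be >= 0")
    return total_mass_ug / (body_weight_kg * n_use_days)


def max_absorbed_dose(d_min: float, f_ue: float) -> float:
    """Upper-bound absorbed dose: d_min corrected for incomplete parent excretion."""
    if not 0 < f_ue <= 1:
        raise TableValidationError(f"F_UE must be in (0, 1], got {f_ue}")
    if d_min < 0:
        raise TableValidationError("d_min must be >= 0")
    return d_min / f_ue


def reconstruct_doses(
    voids: VoidTable,
    participants: dict[str, Participant],
    profiles: dict[str, UseProfile],
    f_ue: dict[str, float],
) -> list[DoseEstimate]:
    """Run the full reconstruction for every participant/analyte present."""
    estimates = []
    for pid in voids.participants:
        part = participants[pid]
        for analyte in sorted(voids.for_participant(pid)["analyte"].unique()):
            mass = excreted_mass(voids, pid, analyte)
            d_min = min_absorbed_dose(mass, part.body_weight_kg, part.n_use_days)
            d_max = max_absorbed_dose(d_min, f_ue[analyte])
            user = pid in profiles and profiles[pid].is_relevant(analyte)
            estimates.append(
                DoseEstimate(
                    participant_id=pid,
                    ingredient=analyte,
                    d_min=d_min,
                    d_max=d_max,
                    user_flag=user,
                )
            )
    return estimates


def summarize_by_use_group(
    estimates: pd.DataFrame, profiles: dict[str, UseProfile]
) -> pd.DataFrame:
    """Group means and sample SDs of D_min by ingredient and user status.

    ``estimates`` needs columns ``participant_id, ingredient, d_min``; the
    user flag is taken from the profiles (a pair is a "user" pair iff at
    least one used product contains the ingredient).  Returns one row per
    (ingredient, group) with group in {users, non_users, all}; the
    non-user row is absent for ingredients everyone used.  SD uses the
    n - 1 denominator and is NaN for single-member groups.
    """
    if estimates.empty:
        raise TableValidationError("empty estimate table")
    missing = [
        pid for pid in estimates["participant_id"].unique() if pid not in profiles
    ]
    if missing:
        raise TableValidationError(f"no use profile for participants: {missing}")

    est = estimates.copy()
    est["user"] = [
        profiles[pid].is_relevant(ing)
        for pid, ing in zip(est["participant_id"], est["ingredient"])
    ]

    rows = []
    for ing, sub in est.groupby("ingredient", sort=True):
        groups = {"users": sub[sub["user"]], "non_users": sub[~sub["user"]], "all": sub}
        for label, g in groups.items():
            if g.empty:
                continue
            values = g["d_min"].to_numpy(dtype=float)
            rows.append(
                dict(
                    ingredient=ing,
                    group=label,
                    mean=float(np.mean(values)),
                    sd=float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan"),
                    n=int(len(values)),
                )
            )
    return pd.DataFrame(rows, columns=["ingredient", "group", "mean", "sd", "n"])
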