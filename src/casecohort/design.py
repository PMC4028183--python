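"""Cohort exclusion flow, sub-cohort selection and case-cohort assembly.

The analysis set of a case-cohort study consists of the centre-stratified
random sub-cohort plus every incident case in the full cohort; each row is
assigned a role (sub-cohort non-case, sub-cohort case, or case outside the
sub-cohort) that the Prentice pseudo-likelihood uses to build risk sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "apply_exclusions",
    "select_subcohort",
    "assemble_analysis_set",
]

ROLES = ("subcohort_noncase", "subcohort_case", "outside_case")


def apply_exclusions(cohort: pd.DataFrame, energy_filter: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove prevalent-disease rows, unknown-status rows and (optionally)
    energy-intake outliers, in that fixed order.

    Unknown disease status is encoded as a missing ``prevalent_flag``.  The
    energy filter keeps rows inside the 1st–99th percentile of
    ``energy_ratio`` (reported energy intake over requirement), percentiles
    computed on the rows still present at that step.  Returns the filtered
    table and a ledger of counts removed per rule in application order.
    """
    ledger = []
    out = cohort
    n0 = len(out)

    prevalent = out["prevalent_flag"].fillna(0).astype(int) == 1
    out = out.loc[~prevalent]
    ledger.append({"rule": "prevalent_disease", "removed": int(prevalent.sum())})

    unknown = out["prevalent_flag"].isna()
    out = out.loc[~unknown]
    ledger.append({"rule": "unknown_status", "removed": int(unknown.sum())})

    if energy_filter:
        if "energy_ratio" not in out.columns:
            raise KeyError("energy filter requires an energy_ratio column")
        lo, hi = np.percentile(out["energy_ratio"].to_numpy(float), [1, 99])
        keep = (out["energy_ratio"] >= lo) & (out["energy_ratio"] <= hi)
        ledger.append({"rule": "energy_ratio_1pct", "removed": int((~keep).sum())})
        out = out.loc[keep]

    ledger_df = pd.DataFrame(ledger)
    ledger_df.attrs["rows_in"] = n0
    ledger_df.attrs["rows_out"] = len(out)
    return out.copy(), ledger_df


def select_subcohort(cohort: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Flag a centre-stratified simple random sub-cohort.

    Within each centre, ``round(fraction * n_centre)`` rows (minimum 1) are
    drawn without replacement, ignoring outcome status — incident cases are
    eligible by design and some will fall in the sub-cohort.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    out = cohort.copy()
    out["subcohort_flag"] = 0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for centre, idx in out.groupby("centre", observed=True, sort=True).groups.items():
        n_centre = len(idx)
        k = max(1, int(round(fraction * n_centre)))
        if k > n_centre:
            k = n_centre
        chosen = rng.choice(np.asarray(idx), size=k, replace=False)
        out.loc[chosen, "subcohort_flag"] = 1
    return out


def assemble_analysis_set(cohort: pd.DataFrame, timescale: str = "age") -> pd.DataFrame:
    """Keep sub-cohort members plus all incident cases and set Prentice roles.

    On the age time scale entry/exit are the ages at entry and exit (left
    truncation at entry age); on the follow-up scale entry is 0 and exit is
    years of follow-up.
    """
    if timescale not in ("age", "followup"):
        raise ValueError("timescale must be 'age' or 'followup'")
    if "subcohort_flag" not in cohort.columns:
        raise KeyError("run select_subcohort first: subcohort_flag missing")
    sub = cohort["subcohort_flag"].astype(int) == 1
    case = cohort["event"].astype(int) == 1
    out = cohort.loc[sub | case].copy()

    bad = out["exit_age"] <= out["entry_age"]
    if bad.any():
        raise ValueError(f"exit_age <= entry_age for participants {out.loc[bad, 'participant_id'].head().tolist()}")

    role = np.where(
        out["subcohort_flag"].astype(int) == 1,
        np.where(out["event"].astype(int) == 1, "subcohort_case", "subcohort_noncase"),
        "outside_case",
    )
    out["role"] = role
    if timescale == "age":
        out["entry_time"] = out["entry_age"].astype(float)
        out["exit_time"] = out["exit_age"].astype(float)
    else:
        out["entry_time"] = 0.0
        out["exit_time"] = (out["exit_age"] - out["entry_age"]).astype(float)
    out.attrs["timescale"] = timescale
    return out
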