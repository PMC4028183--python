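"""Tab-delimited table I/O, result formatting and run metadata.

One dialect everywhere: tab-separated text with a header row and the string
``NA`` as the missing-value sentinel.  Cohort tables are validated on read
(required columns, event in {0,1}, dosages in {0,1,2,NA}) with errors that
name the offending column and row.  Result writers use a deterministic
column order and fixed formatting (two decimals for HRs and CIs, scientific
notation for p-values) and record a run-metadata sidecar with the config
hash, seed and library versions so every output is reproducible from its
inputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GENOTYPE_PREFIX

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_locus_table",
    "write_results",
    "run_metadata",
    "CohortFormatError",
]

NA = "NA"
REQUIRED_COHORT_COLUMNS = [
    "participant_id",
    "country",
    "centre",
    "sex",
    "entry_age",
    "exit_age",
    "event",
    "subcohort_flag",
]


class CohortFormatError(ValueError):
    pass


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a tab-delimited cohort table."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            raise CohortFormatError(f"missing required column {col!r} in {path}")
    ev = df["event"]
    bad = ~ev.isin([0, 1])
    if bad.any():
        row = int(np.where(bad)[0][0])
        raise CohortFormatError(f"invalid event value {ev.iloc[row]!r} at row {row}, column 'event'")
    for col in df.columns:
        if col.startswith(GENOTYPE_PREFIX):
            vals = df[col]
            bad = vals.notna() & ~vals.isin([0, 1, 2])
            if bad.any():
                row = int(np.where(bad)[0][0])
                raise CohortFormatError(
                    f"invalid dosage {vals.iloc[row]!r} at row {row}, column {col!r}"
                )
    if "prevalent_flag" in df.columns:
        df["prevalent_flag"] = df["prevalent_flag"].astype("Int64")
    return df


def write_cohort(df: pd.DataFrame, path, config: dict | None = None, seed: int | None = None) -> None:
    """Write a cohort table; a ``.meta.json`` sidecar records the generating
    configuration when given."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
    if config is not None or seed is not None:
        meta = run_metadata(config or {}, seed)
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_locus_table(path) -> pd.DataFrame:
    from .loci import validate_locus_table

    return validate_locus_table(pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False))


def _fmt(x, kind):
    if pd.isna(x):
        return NA
    if kind == "hr":
        return f"{x:.2f}"
    if kind == "p":
        return f"{x:.2e}"
    if kind == "beta":
        return f"{x:.4f}"
    return str(x)


def write_results(results: pd.DataFrame, path, config: dict | None = None, seed: int | None = None) -> None:
    """Write an estimate table with deterministic order and formatting.

    HR/CI columns get two decimals, p-values scientific notation
    (0.000146 -> ``1.46e-04``), coefficients/SEs four decimals; column order
    follows the input.  Identical inputs and config produce byte-identical
    files.
    """
    if len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    out = results.copy()
    for col in out.columns:
        low = col.lower()
        if low in ("hr", "ci_low", "ci_high", "incidence_pct"):
            out[col] = [_fmt(v, "hr") for v in out[col]]
        elif low in ("p", "p_value", "threshold"):
            out[col] = [_fmt(v, "p") for v in out[col]]
        elif low in ("beta", "se", "tau2", "i2", "incidence", "mc_se"):
            out[col] = [_fmt(v, "beta") for v in out[col]]
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)
    meta = run_metadata(config or {}, seed)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_metadata(config: dict, seed: int | None = None) -> dict:
    from . import __version__

    return {
        "config": {k: v for k, v in config.items() if not isinstance(v, pd.DataFrame)},
        "config_hash": _config_hash({k: v for k, v in config.items() if not isinstance(v, pd.DataFrame)}),
        "seed": seed,
        "versions": {
            "casecohort": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
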