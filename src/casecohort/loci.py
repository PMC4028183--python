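"""Bundled locus metadata for the 49-SNP type 2 diabetes risk score.

``load_t2d_loci`` returns the locus table used throughout the examples and
the simulator: locus identifier, SNP rsID, risk allele, per-allele hazard
ratio and log-scale weight as published for these 49 established T2D
susceptibility loci, plus a ``risk_allele_frequency`` column.

The frequencies and the non-risk (``other_allele``) bases are SYNTHETIC
stand-ins (the source table does not print them): frequencies were
calibrated once so that the unweighted 49-locus risk-allele count has mean
~52 and standard deviation ~4.4 alleles under Hardy–Weinberg proportions,
matching the reported score distribution (range 36–68, quartile cutoffs
near 49/52/55).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_t2d_loci", "validate_locus_table"]

REQUIRED_COLUMNS = ["locus_id", "risk_allele", "other_allele", "weight", "risk_allele_frequency"]


def validate_locus_table(loci: pd.DataFrame) -> pd.DataFrame:
    """Check the locus-table invariants; returns the table unchanged."""
    for col in REQUIRED_COLUMNS:
        if col not in loci.columns:
            raise ValueError(f"locus table missing column {col!r}")
    if loci["locus_id"].duplicated().any():
        dup = loci.loc[loci["locus_id"].duplicated(), "locus_id"].tolist()
        raise ValueError(f"duplicate locus_ids: {dup}")
    f = loci["risk_allele_frequency"]
    if not ((f > 0) & (f < 1)).all():
        raise ValueError("risk_allele_frequency must lie strictly in (0, 1)")
    if not loci["weight"].map(lambda x: pd.notna(x) and abs(x) < float("inf")).all():
        raise ValueError("weights must be finite")
    return loci


def load_t2d_loci() -> pd.DataFrame:
    path = resources.files("casecohort.data").joinpath("t2d_loci_synthetic.tsv")
    with resources.as_file(path) as p:
        loci = pd.read_csv(p, sep="\t")
    return validate_locus_table(loci)
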