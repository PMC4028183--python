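"""Genetic risk score construction from risk-allele dosages.

Implements the scoring pipeline for a multi-locus susceptibility score:
orienting dosages to the risk allele, case/non-case mean imputation of
sporadically missing genotypes (individuals genotyped at fewer than
``min_genotyped`` loci are excluded rather than imputed), unweighted
(risk-allele count) or externally weighted scores, standardisation and
quartile assignment against a reference subset (the random sub-cohort), and
a per-locus Hardy–Weinberg equilibrium goodness-of-fit test for genotype QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "orient_dosages",
    "impute_missing_dosages",
    "compute_score",
    "hwe_test",
    "HWEResult",
]


class GenotypeDataError(ValueError):
    pass


def orient_dosages(
    genotypes: pd.DataFrame,
    loci: pd.DataFrame,
    counted_allele_map: dict | None = None,
) -> pd.DataFrame:
    """Re-express dosages as risk-allele counts.

    ``counted_allele_map`` gives, per locus, the allele the stored dosage
    counts; loci whose counted allele is the non-risk allele are flipped
    ``d -> 2 - d``.  Missing entries stay missing.  Absent map entries are
    taken as already risk-allele counted.
    """
    counted_allele_map = counted_allele_map or {}
    loci = loci.set_index("locus_id")
    out = genotypes.copy().astype(float)
    for lid, counted in counted_allele_map.items():
        if lid not in loci.index:
            raise GenotypeDataError(f"unknown locus {lid!r} in counted_allele_map")
        risk = loci.at[lid, "risk_allele"]
        other = loci.at[lid, "other_allele"]
        if counted == risk:
            continue
        if counted != other:
            raise GenotypeDataError(
                f"locus {lid!r}: counted allele {counted!r} matches neither "
                f"{risk!r} nor {other!r}"
            )
        out[lid] = 2.0 - out[lid]
    return out


def impute_missing_dosages(
    genotypes: pd.DataFrame,
    case_status: np.ndarray | pd.Series,
    min_genotyped: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Case/non-case mean imputation of sporadically missing dosages.

    Individuals genotyped at fewer than ``min_genotyped`` loci (default
    L - 2, the generalisation of a 47-of-49 completeness rule) are flagged
    excluded and left untouched.  For included individuals each missing cell
    is replaced by the mean observed dosage at that locus among individuals
    of the same case status; observed cells are never altered, so per-locus,
    per-status observed means are preserved exactly.
    """
    case = np.asarray(case_status).astype(bool)
    if len(case) != len(genotypes):
        raise GenotypeDataError("case_status length must match genotype rows")
    L = genotypes.shape[1]
    if min_genotyped is None:
        min_genotyped = L - 2
    if min_genotyped > L:
        raise GenotypeDataError("min_genotyped cannot exceed the number of loci")
    G = genotypes.to_numpy(float)
    n_typed = (~np.isnan(G)).sum(axis=1)
    included = n_typed >= min_genotyped
    out = G.copy()
    for status in (False, True):
        rows = included & (case == status)
        if not rows.any():
            continue
        block = out[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        obs = np.isnan(G[case == status])
        fully_missing = obs.all(axis=0)
        if fully_missing.any():
            lid = genotypes.columns[np.where(fully_missing)[0][0]]
            grp = "cases" if status else "non-cases"
            raise GenotypeDataError(f"locus {lid!r} entirely missing among {grp}")
        col_means = np.nanmean(G[case == status], axis=0)
        block[miss] = np.broadcast_to(col_means, block.shape)[miss]
        out[rows] = block
    return pd.DataFrame(out, index=genotypes.index, columns=genotypes.columns), included


def compute_score(
    genotypes: pd.DataFrame,
    loci: pd.DataFrame,
    weighted: bool = False,
    reference_rows: np.ndarray | pd.Index | None = None,
    included: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw, standardised and quartile-coded scores per individual.

    raw_score is the (weighted) sum of risk-allele dosages.  The
    standardisation mean/SD (sample SD, ddof=1) and the quartile cutoffs
    (25/50/75 percentiles; left-closed right-open intervals, boundary ties
    to the upper quartile) come from ``reference_rows`` only — the random
    sub-cohort — and are then applied to every included row.
    """
    loci = loci.set_index("locus_id").loc[genotypes.columns]
    if included is None:
        included = ~genotypes.isna().any(axis=1).to_numpy()
    included = np.asarray(included, bool)
    G = genotypes.to_numpy(float)
    if np.isnan(G[included]).any():
        raise GenotypeDataError("missing dosages remain among included rows; impute first")
    w = loci["weight"].to_numpy(float) if weighted else np.ones(len(loci))
    raw = np.where(included, np.nansum(G * w, axis=1), np.nan)

    if reference_rows is None:
        ref_mask = included
    else:
        ref = pd.Index(genotypes.index).isin(pd.Index(reference_rows))
        ref_mask = ref & included
    if not ref_mask.any():
        raise GenotypeDataError("reference subset is empty after exclusions")
    ref_scores = raw[ref_mask]
    mu = float(np.mean(ref_scores))
    sd = float(np.std(ref_scores, ddof=1))
    cuts = np.percentile(ref_scores, [25, 50, 75])
    # a degenerate reference (all scores equal) has no SD scale
    std = (raw - mu) / sd if sd > 0 else np.full_like(raw, np.nan)
    quart = np.where(included, 1 + np.searchsorted(cuts, raw, side="right"), -1)

    out = pd.DataFrame(
        {
            "raw_score": raw,
            "standardized_score": std,
            "quartile": pd.array(np.where(included, quart, np.nan), dtype="Int64"),
            "n_genotyped": (~np.isnan(G)).sum(axis=1),
            "included_flag": included.astype(int),
        },
        index=genotypes.index,
    )
    out.attrs["reference_mean"] = mu
    out.attrs["reference_sd"] = sd
    out.attrs["quartile_cutoffs"] = cuts.tolist()
    return out


@dataclass
class HWEResult:
    statistic: float
    p_value: float
    monomorphic: bool = False


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> HWEResult:
    """1-df chi-square goodness of fit of genotype counts to Hardy–Weinberg
    proportions at the estimated allele frequency.

    A monomorphic locus has no degrees of freedom to test; its statistic is
    defined as 0 and flagged.
    """
    counts = np.array([n_hom_risk, n_het, n_hom_other], float)
    if (counts < 0).any() or counts.sum() <= 0:
        raise GenotypeDataError("genotype counts must be non-negative with positive total")
    n = counts.sum()
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(statistic=0.0, p_value=1.0, monomorphic=True)
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    if stat < 1e-12:  # exact HWE proportions up to float rounding
        stat = 0.0
    return HWEResult(statistic=stat, p_value=float(stats.chi2.sf(stat, df=1)))
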