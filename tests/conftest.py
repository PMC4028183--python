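import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import casecohort as cc


def clean_config(**kw):
    """Simulation config with all optional structure switched off, so the
    only effects present are the ones a test asks for."""
    defaults = dict(
        covariate_effects={},
        interaction_effect=0.0,
        country_effect_sd=0.0,
        prevalent_fraction=0.0,
        unknown_status_fraction=0.0,
    )
    defaults.update(kw)
    return cc.SimulationConfig(**defaults)


def single_locus(freq=0.3):
    return pd.DataFrame(
        {
            "locus_id": ["L1"],
            "risk_allele": ["A"],
            "other_allele": ["G"],
            "weight": [np.log(1.08)],
            "risk_allele_frequency": [freq],
        }
    )


@pytest.fixture(scope="session")
def default_cohort():
    return cc.simulate_cohort(cc.SimulationConfig(n_individuals=6000, seed=11))


@pytest.fixture(scope="session")
def analysis_set(default_cohort):
    kept, _ = cc.apply_exclusions(default_cohort)
    sel = cc.select_subcohort(kept, 0.08, seed=12)
    return cc.assemble_analysis_set(sel, timescale="age")


def r_coxph_oracle(df: pd.DataFrame, covariates: list[str], tmp_path):
    """Independent Cox oracle: R survival::coxph with Breslow ties, cluster-
    robust variance.  Returns (beta, naive_se, robust_se) arrays."""
    data_path = tmp_path / "oracle_data.tsv"
    out_path = tmp_path / "oracle_out.tsv"
    df[["entry_time", "exit_time", "event"] + covariates].to_csv(data_path, sep="\t", index=False)
    script = textwrap.dedent(
        f"""
        library(survival)
        d <- read.delim("{data_path}")
        d$rid <- seq_len(nrow(d))
        f <- coxph(Surv(entry_time, exit_time, event) ~ {' + '.join(covariates)},
                   data = d, ties = "breslow", robust = TRUE, cluster = rid)
        out <- data.frame(beta = coef(f),
                          naive_se = sqrt(diag(f$naive.var)),
                          robust_se = sqrt(diag(vcov(f))))
        write.table(out, "{out_path}", sep = "\\t", row.names = FALSE)
        """
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    out = pd.read_csv(out_path, sep="\t")
    return out["beta"].to_numpy(), out["naive_se"].to_numpy(), out["robust_se"].to_numpy()
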