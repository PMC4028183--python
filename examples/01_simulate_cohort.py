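"""Generate a synthetic multi-country cohort and inspect its calibration.

Builds a 20,000-person cohort across 8 countries with genotypes at 49 risk
loci, lifestyle covariates and incident events on the age time scale, then
writes it to tab-delimited text with a metadata sidecar.
"""

from pathlib import Path

import casecohort as cc
from casecohort.io import write_cohort

cfg = cc.SimulationConfig(n_individuals=20_000, seed=42)
cohort = cc.simulate_cohort(cfg)

person_years = (cohort["exit_age"] - cohort["entry_age"]).sum()
rate = 1000 * cohort["event"].sum() / person_years
print(f"participants: {len(cohort)}, incident cases: {cohort['event'].sum()}")
print(f"event rate: {rate:.2f} per 1,000 person-years "
      "(the generator is calibrated near 3.8 at the null)")
print(f"mean follow-up: {(cohort['exit_age'] - cohort['entry_age']).mean():.1f} y")
print(cohort[["participant_id", "country", "sex", "entry_age", "exit_age", "event", "bmi_group"]].head())

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
write_cohort(cohort, out / "synthetic_cohort.tsv", config={"n_individuals": cfg.n_individuals}, seed=cfg.seed)
print(f"written to {out / 'synthetic_cohort.tsv'} (+ .meta.json sidecar)")
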