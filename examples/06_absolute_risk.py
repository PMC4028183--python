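"""Absolute 10-year cumulative incidence by score quartile and BMI group.

Reconstructs the full cohort by stratified resampling with replacement from
the sub-cohort and applies Kaplan–Meier within each (quartile x BMI group)
stratum: relative genetic risk translates into small absolute differences
compared with the dominant effect of adiposity.
"""

import casecohort as cc

cfg = cc.SimulationConfig(n_individuals=80_000, seed=33)
cohort = cc.simulate_cohort(cfg)
kept, _ = cc.apply_exclusions(cohort)
selected = cc.select_subcohort(kept, fraction=0.05, seed=34)
sub = selected[selected["subcohort_flag"] == 1]

scores = cc.compute_score(
    cc.genotype_matrix(selected), cfg.loci, reference_rows=sub["participant_id"]
)

tab = cc.incidence_by_strata(
    sub, scores, factor="bmi_group", horizon=10.0,
    target_n=len(kept), replicates=30, seed=35,
)
tab["incidence_pct"] = 100 * tab["incidence"]
tab["mc_se_pct"] = 100 * tab["mc_se"]
labels = {0: "normal weight", 1: "overweight", 2: "obese"}
tab["stratum"] = tab["level"].map(labels)
print("10-year cumulative incidence (%) by genetic-score quartile and BMI group")
print("(mean over 30 stratified reconstructions; mc_se_pct is the Monte-Carlo SE):")
print(
    tab[["stratum", "quartile", "n_subcohort", "incidence_pct", "mc_se_pct"]]
    .round({"incidence_pct": 2, "mc_se_pct": 3})
    .to_string(index=False)
)
lowest = tab[(tab["level"] == 0) & (tab["quartile"] == 1)]["incidence_pct"].iloc[0]
highest = tab[(tab["level"] == 2) & (tab["quartile"] == 4)]["incidence_pct"].iloc[0]
print(f"\nnormal-weight lowest-quartile risk {lowest:.2f}% vs obese top-quartile {highest:.2f}%: "
      "lifestyle dominates absolute risk even when relative genetic effects are strong")
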