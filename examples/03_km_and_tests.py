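"""Kaplan-Meier estimation and arm comparison for time to CPC remission.

Derives time to CPC remission (closure of all external openings plus PDAI
pain = 0 and discharge = 0) from the pooled registry and compares the DVS
and SoC arms with the log-rank and Peto-Peto tests.
"""

from cpfextrap import (
    CohortConfig,
    apply_exclusions,
    derive_remission,
    generate_cohort,
    km_estimate,
    two_sample_test,
)

dvs, soc = apply_exclusions(generate_cohort(CohortConfig(seed=21)))
samples = {"DVS": derive_remission(dvs.records, "cpc"),
           "SoC": derive_remission(soc.records, "cpc")}

for arm, df in samples.items():
    est = km_estimate(df["time"], df["event"])
    med = "not reached" if est.median is None else f"{est.median:.0f} weeks"
    print(f"{arm}: n={est.n}, events={int(df['event'].sum())}, "
          f"median time to CPC remission {med}, RMST({est.rmst['horizon']:.0f}w) "
          f"{est.rmst['value']:.1f} weeks")

for method in ("LOGRANK", "GEHAN_WILCOXON_PETO"):
    r = two_sample_test(samples["DVS"]["time"], samples["DVS"]["event"],
                        samples["SoC"]["time"], samples["SoC"]["event"], method)
    print(f"{method}: chi2(1) = {r.statistic:.2f}, p = {r.p_value:.2g}")
# Smaller median / larger chi-square for DVS reflects the faster remission
# built into the generating model for the active arm.
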