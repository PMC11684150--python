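"""Location- and shape-adjusted parametric fits with AIC/BIC selection.

Fits the five candidate families to time to CPC remission in the SoC arm
with a 4-week lead-in, age and luminal-disease activity in the location
linear predictor and luminal activity also in the shape predictor, then
ranks them by AIC.
"""

from cpfextrap import (
    CohortConfig,
    FamilySpec,
    apply_exclusions,
    apply_lead_in,
    compare_models,
    derive_remission,
    fit_mle,
    generate_cohort,
    predict_curve,
)

_, soc = apply_exclusions(generate_cohort(CohortConfig(seed=31)))
samples = apply_lead_in(derive_remission(soc.records, "cpc"), lead_in_weeks=4.0)

fits = []
for family in ("weibull", "gompertz", "gengamma", "loglogistic", "lognormal"):
    spec = FamilySpec(family, ("age_c", "luminal_active"), ("luminal_active",))
    fits.append(fit_mle(samples, spec, auto_drop_shape=True))

table = compare_models(fits)
print(table.to_string(index=False))

best = min(fits, key=lambda f: f.aic)
curve = predict_curve(best, {"age_c": 0.0, "luminal_active": 0.0}, horizon_weeks=208)
print(f"\nbest family by AIC: {best.spec.family}")
for week in (4, 26, 52, 104, 208):
    s = float(curve.loc[curve['week'] == week, 'survival'].iloc[0])
    print(f"  P(not yet in CPC remission) at week {week:>3}: {s:.3f}")
# S(t) = 1 up to the 4-week lead-in, then the extrapolated curve falls as
# patients reach remission; AIC differences of >2 are conventionally
# meaningful, and the generating family should rank at or near the top.
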