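"""Cone-survival decay kinetics and treatment effect sizes.

Simulates cone-density measurements (cones per 100 µm at four retinal
eccentricities, 6 eyes per arm) for a control-like and a treated-like decay
arm, fits the log2-linear exponential decay per arm, extrapolates the day
each fitted curve crosses 1 cone/100 µm, and quantifies the treatment effect
on per-animal log2 survival ratios with shared-control Hedges' g estimation
(5000 bootstrap resamples, permutation p values).
"""

from retinakit import kinetics, synth

# the treated arm both starts no better and decays more slowly, so the
# per-animal survival ratio widens with age
models = [
    synth.DecayModel(a=5.541, b=0.05832, noise_cv=0.1, arm_label="control"),
    synth.DecayModel(a=5.541, b=0.04000, noise_cv=0.1, arm_label="treated"),
]
ages = [26, 30, 37, 45, 60, 90]
records = synth.simulate_survival(models, ages=ages, n_eyes=6, seed=1)
series = kinetics.aggregate(records)

fits = {arm: kinetics.fit_decay(series, arm, theta=1.0) for arm in ("control", "treated")}
for arm, fit in fits.items():
    print(
        f"{arm:8s}: log2 density = {fit.a:.3f} - {fit.b:.5f} * day  "
        f"(r2 = {fit.r2:.4f}), extinction day ~ {fit.x_intercept:.1f}"
    )
delay = kinetics.intercept_delay(fits["control"], fits["treated"])
print(f"separation of the extinction days: {delay:.1f} days")

# effect sizes of the survival ratio vs the earliest stage
ratios = kinetics.survival_ratio(records)
ctrl = ratios.loc[ratios["age_pn"] == 26, "log2_ratio"].to_numpy()
groups = {
    f"PN{int(age)}": sub["log2_ratio"].to_numpy()
    for age, sub in ratios.groupby("age_pn")
    if age != 26
}
print("\nshared-control Hedges' g of log2 survival ratios vs PN26:")
for res in kinetics.shared_control_estimation(ctrl, groups, n_boot=5000, n_perm=5000, seed=2):
    print(
        f"  {res.comparison_label}: g = {res.hedges_g:+.2f} "
        f"[{res.ci_low:+.2f}, {res.ci_high:+.2f}], p_perm = {res.p_perm:.3f}"
    )
print(
    "\nThe extinction-day separation measures how much longer the treated "
    "arm retains cones; growing |g| across stages measures the widening of "
    "the survival-ratio distributions relative to the shared early control."
)
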