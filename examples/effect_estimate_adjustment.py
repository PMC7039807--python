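"""Convert a pooled relative risk to a slope and adjust it for infiltration.

The pooled cohort estimate (RR 1.073 per 10 ug/m3 outdoor PM2.5) is
converted to a log-linear slope, then divided by the population
time-weighted infiltration sum so it applies to microenvironmental
exposure rather than outdoor concentration alone.
"""

from pmburden import (
    EffectEstimate,
    InfiltrationProfile,
    modify_beta,
    rr_to_beta,
    weighted_infiltration_sum,
)

raw = EffectEstimate(
    beta=rr_to_beta(1.073, per=10),
    ci_low=rr_to_beta(1.037, per=10),
    ci_high=rr_to_beta(1.11, per=10),
)
print(f"raw slope: {raw.beta:.4f} (95% CI {raw.ci_low:.4f}-{raw.ci_high:.4f}) per ug/m3")

profile = InfiltrationProfile(
    infiltration={"residence": 0.55, "other_indoor": 0.60, "vehicle": 0.70},
    time_fractions={"residence": 0.687, "other_indoor": 0.182,
                    "vehicle": 0.055, "outdoor": 0.076},
)
sum_ft = weighted_infiltration_sum(profile)
print(f"time-weighted infiltration sum: {sum_ft:.4f}")

mod = modify_beta(raw, 0.60)
print(f"modified slope: {mod.beta:.4f} (95% CI {mod.ci_low:.4f}-{mod.ci_high:.4f}) per ug/m3")
print("-> risk per unit of actual microenvironmental exposure is ~1.7x the")
print("   per-unit-outdoor-concentration slope, because only ~60% of outdoor")
print("   PM2.5 reached the cohorts across the places they spent time.")
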