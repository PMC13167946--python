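"""Trial-design statistics: power analysis, contingency tables, effect sizes.

These are fully determined by printed summary numbers, so the outputs
can be checked against the trial's reported values directly.
"""

from nirsvft.clinical import (
    between_group_change_from_ci,
    chi_square_2x2,
    inflate_dropout,
    proportion_pct,
    sample_size_two_t,
)

# Sample size: pilot PSQI improvements of 5.19 vs 2.37 points, sd 3.02,
# two-sided alpha .05, power .95, then 20% dropout inflation.
n = sample_size_two_t(5.19, 2.37, 3.02, alpha=0.05, power=0.95)
n_inflated, total = inflate_dropout(n, 0.20)
print(f"required sample size: {n} per group; with 20% dropout: "
      f"{n_inflated} per group, {total} total")

# Blinding assessment: correct-guess rates and their 2x2 chi-square.
print(f"\nblinding guess rates: intervention {proportion_pct(15, 32)}%, "
      f"control {proportion_pct(14, 32)}%")
chi2, p, _ = chi_square_2x2([[15, 17], [14, 18]])
print(f"chi-square (no continuity correction): chi2 = {chi2:.3f}, p = {p:.3f}")

chi2, p, _ = chi_square_2x2([[4, 28], [3, 29]])
print(f"adverse events: chi2 = {chi2:.3f}, p = {p:.3f}")

# Effect sizes recovered from published change means + 95% CIs (n=32/group).
psqi = between_group_change_from_ci(-4.69, (-6.04, -3.33), 32,
                                    -2.13, (-2.83, -1.42), 32)
print(f"\nPSQI total between-group Cohen's d = {psqi.effect_size:.3f} "
      f"(95% CI {psqi.effect_ci[0]:.3f} to {psqi.effect_ci[1]:.3f})")
sds = between_group_change_from_ci(-7.78, (-10.54, -5.02), 32,
                                   -3.31, (-6.22, -0.41), 32)
print(f"SDS between-group Cohen's d = {sds.effect_size:.3f} "
      f"(95% CI {sds.effect_ci[0]:.3f} to {sds.effect_ci[1]:.3f})")
print("(negative d: the intervention group improved more)")
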