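"""Bout-duration analysis: log-linear model with a time x treatment test.

Bout durations are heavily right skewed, so they are modelled on the log
scale with treatment, hour and their interaction as categorical effects
plus a subject blocking effect.  The interaction F test asks whether the
time course of durations differs between treatments; cell-wise predicted
means with 95% CIs (back-transformed to seconds) show where.
"""

import numpy as np

import sleepbouts as sb

study = sb.simulate_study(sb.default_config(seed=1))
table = sb.bout_table(study)

for state in ("PW", "S1"):
    fit = sb.fit_duration_model(table, state)
    print(f"\n{state}: interaction F = {fit.f_stat:.2f} "
          f"(df {fit.df_num}, {fit.df_den}), p = {fit.p_value:.3f}")
    print(f"  {'treatment':>9} {'hour':>4} {'mean [s]':>9} {'95% CI [s]':>18} {'n':>5}")
    for _, r in fit.cells.iterrows():
        lo, hi = np.exp(r.ci_low), np.exp(r.ci_high)
        print(f"  {r.treatment:>9} {int(r.bin) + 1:>4} "
              f"{np.exp(r.mean_log):9.1f} [{lo:7.1f}, {hi:7.1f}] {int(r.n_obs):>5}")

print("\nDwell mixtures are shared across simulated treatments, so the "
      "interaction should be non-significant: the drug mechanism here is "
      "transition frequency, not bout duration.")
print(f"\nPK context: a drug with a 22-h half-life declines only "
      f"{sb.pk_decline_percent(22, 3):.1f}% over the 3-h observation window, "
      "so time trends are not elimination artefacts.")
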