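"""Full study analysis: epochs, mixed models, and the condition-smooth tests.

A coupled study is generated (envelope gain bump of 0.3 at leg-strength
acceleration peaks only), analysed end-to-end, and the two inferential
stages are printed: linear mixed models of the 50 ms peak-window magnitudes,
and the factor-smooth tests of the +/-200 ms epoch curves against the
surrogate armBlock condition.
"""

from limbspeech import CouplingParams, StudyConfig, analyze_study, simulate_study

config = StudyConfig(
    n_participants=8,
    n_female=6,
    trial_duration=60.0,
    coupling=CouplingParams(env_bump_amplitude=0.3, bump_width=0.04, accel_threshold=3.4),
    mode="tracks",
)
bundle = simulate_study(config, seed=11)
res = analyze_study(bundle, seed=11, fit_f0_models=False)

pm = res.peak_measures
print(f"{len(pm)} retained acceleration peaks across "
      f"{pm['participant_id'].nunique()} participants")
if res.duration_correlation is not None:
    c = res.duration_correlation
    print(f"arm-leg cadence correlation: r2 = {c.r2:.2f}, "
          f"t = {c.statistic:.2f}, df = {int(c.df_den)}, p = {c.p_parametric:.2g}")
if res.lmm_env is not None:
    t = res.lmm_env.term("acc_peak_magnitude")
    print(f"envelope LMM: acceleration coefficient {t['estimate']:+.4f} "
          f"(se {t['se']:.4f}, p = {t['p']:.2g})")

print("\nsmooth-term tests (envelope, z-scaled):")
print(res.tests_frame()[["test", "statistic", "edf", "p"]].to_string(index=False))
# Expected pattern: the legMot-armBlock difference smooth is significant (the
# injected bump applies at leg-strength impulses) while armMot-armBlock mostly
# is not.  The LMM slope also turns positive here: gating the bump on a
# magnitude threshold makes high-impulse peaks louder on average, a step
# relation the linear model picks up.
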