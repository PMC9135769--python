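"""Fit a simulated SPR titration and recover binding constants.

Simulates five noise-free association curves with the published rate
constants of a designed four-helix-bundle cytokine variant
(k_a = 3.8e4 M^-1 s^-1, k_d = 6.1e-3 s^-1) across a 2-fold concentration
series, fits each to Gamma(t) = c + a*exp(-b*t) by bounded Nelder-Mead
chi-square minimisation, regresses k_obs on concentration, and reports
K_d = k_d/k_a with leave-one-concentration-out jackknife dispersions.
"""

from topofold import analyze_titration, make_titration, round_sig

curves = make_titration(k_a=3.8e4, k_d=6.1e-3)  # 5-80 nM, 180 s, 900 points
summary = analyze_titration(curves)

print("concentration (nM)   k_obs (s^-1)")
for c, k in zip(summary.concentrations, summary.k_obs):
    print(f"{c * 1e9:18.0f}   {k:.4e}")

print(f"\nk_a = {summary.k_a:.3e} M^-1 s^-1  (jackknife s = {summary.s_ka:.1e})")
print(f"k_d = {summary.k_d:.3e} s^-1        (jackknife s = {summary.s_kd:.1e})")
print(f"K_d = {round_sig(summary.K_d, 2):.1e} M          (jackknife s = {summary.s_Kd:.1e})")

# k_obs grows linearly with concentration (k_obs = k_a*C + k_d); the slope
# and intercept of that line are the association and dissociation rates, and
# their quotient k_d/k_a = 1.6e-7 M recovers the generating affinity. With
# noise-free input the jackknife dispersions collapse to ~0.
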