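"""Hill-number diversity with estimation, rarefaction and bootstrap errors.

q=0 is species richness; q=1 the exponential Shannon entropy (the effective
number of common species). The asymptotic estimates correct for undetected
rare species via singleton/doubleton frequencies (Chao1 and the
singleton-corrected entropy estimator).
"""

from meiobar import chao1, estimate, hill_observed

x = [25, 12, 8, 5, 3, 2, 1, 1, 1]   # one slice's combined integer abundances

print(f"observed richness        D0 = {hill_observed(x, 0):.1f}")
print(f"observed exp-Shannon     D1 = {hill_observed(x, 1):.3f}")
print(f"Chao1 estimated richness    = {chao1(x):.2f}")

est = estimate(x, q=0, B=200, seed=7)
print(f"bootstrap SE = {est.se:.2f}, 95% CI = "
      f"({est.ci95[0]:.1f}, {est.ci95[1]:.1f})")
curve = est.curve
print("rarefaction/extrapolation (m, expected richness):")
print(curve[["m", "diversity", "extrapolated"]].round(2).to_string(index=False))
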