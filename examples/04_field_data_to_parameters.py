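"""Recover the model configuration from (synthetic) field measurements.

Generates seeded stand-ins for the field campaign — paired
benthic/emergence samples, pan-trap and litter-trap flux series, and
biomass surveys — then recapitulates the empirical parameterization:
the emergence coefficient from a zero-intercept regression, the subsidy
fluxes from trap means, and the starting pools from survey means.
"""

from streamweb import parameterize_from_fixtures
from streamweb.fielddata import generate_all_fixtures

for label, cv in (("noiseless", 0.0), ("10% sampling noise", 0.10)):
    fixtures = generate_all_fixtures(seed=12, uniform_cv=cv)
    result = parameterize_from_fixtures(fixtures)
    p, s = result.params, result.initial_state
    fit = result.emergence_fit
    print(f"--- {label}")
    print(f"  e_h = {fit.slope:.5f} day⁻¹  "
          f"(95% CI {fit.ci95()[0]:.5f}–{fit.ci95()[1]:.5f}, n={fit.n})")
    print(f"  X = {p.X:.4f}, I = {p.I:.3f} g·m⁻²·day⁻¹")
    print(f"  starting pools: A={s.A:.3f}, H={s.H:.4f}, G={s.G:.4f}, "
          f"T={s.T:.2f}, S={s.S:.2f} g·m⁻²")
    print(f"  still needing calibration: {result.needs_calibration}\n")

print("Noiseless fixtures reproduce the printed configuration exactly; "
      "realistic sampling noise moves each recovered value by a few "
      "percent (the survey means average 32 replicate samples).")
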