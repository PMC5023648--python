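"""Mid-domain-effect null: random range placement inside hard boundaries.

Keeping every species' range size but randomising its position forces
high expected richness at mid elevations purely by geometry. The
simulated mean is checked against the exact closed-form expectation.
"""

import numpy as np

import altiband as ab

checklist = ab.generate_checklist(ab.ChecklistParams(seed=42), (1350.0, 5050.0))
ranges = (checklist["elev_max"] - checklist["elev_min"]).to_numpy()
scheme = ab.make_equal_elevation_bands(1350, 5050, 100)

pred = ab.simulate_mde(ranges, (1350, 5050), scheme, n_sim=1000, seed=7)
exact = ab.analytic_mde_expectation(ranges, scheme, (1350, 5050))

peak_band = int(pred.mean_richness.argmax())
print(f"{pred.n_species} ranges placed 1000 times over {scheme.n_bands} bands")
print(f"MDE predicted richness peaks in band {peak_band + 1} "
      f"(mid {scheme.mids[peak_band]:.0f} m) with {pred.mean_richness.max():.1f} "
      "species on average -> the geometric mid-domain hump")
print(f"edge bands expect only {pred.mean_richness[0]:.1f} and "
      f"{pred.mean_richness[-1]:.1f} species")

z = np.abs(pred.mean_richness - exact) / np.maximum(pred.standard_error(), 1e-12)
print(f"\nworst |z| between simulation and closed form: {z.max():.2f} "
      "over 37 bands (values near 3 arise by chance among this many comparisons)")
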