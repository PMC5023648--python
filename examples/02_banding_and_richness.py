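"""Build both band schemes and count interpolated richness along each.

Equal-elevation bands have fixed 100-m width but wildly different areas;
equal-area bands hold (almost) the same number of DEM cells each, so
their widths stretch where land is scarce. Re-counting richness on the
equal-area scheme is area correction "method 2".
"""

import altiband as ab

params = ab.MountainParams(seed=42)
grid = ab.generate_climate(ab.generate_elevation_grid(params), params)
checklist = ab.generate_checklist(ab.ChecklistParams(seed=42), (1350.0, 5050.0))

ee = ab.make_equal_elevation_bands(1350, 5050, 100)
ee = ab.summarize_band_climate(ab.assign_band_areas(ee, grid), grid)
ea = ab.make_equal_area_bands(grid, 37, seed=1, domain=(1350, 5050))
ea = ab.summarize_band_climate(ea, grid)

print(f"equal-elevation: {ee.n_bands} bands, areas "
      f"{ee.bands['area_km2'].min():.3f}-{ee.bands['area_km2'].max():.3f} km^2")
print(f"equal-area: {ea.n_bands} bands, widths "
      f"{ea.bands['width_m'].min():.1f}-{ea.bands['width_m'].max():.1f} m "
      "(narrowest where the mountain is broadest)")

obs = ab.richness_table(checklist, ee)
cor2 = ab.richness_table(checklist, ea)
peak_obs = ee.mids[obs["S"].to_numpy().argmax()]
peak_cor2 = ea.mids[cor2["S"].to_numpy().argmax()]
print(f"\nobserved species richness peaks at {peak_obs:.0f} m "
      f"(max S = {obs['S'].max()})")
print(f"equal-area (method 2) richness peaks at {peak_cor2:.0f} m "
      f"(max S = {cor2['S'].max()})")
print("both are interior peaks -> the hump survives the area correction")

subset = ab.single_band_subset(checklist, ee)
print(f"\n{len(subset)} species occupy a single band; counting them needs "
      "no interpolation (interpolation-artefact probe)")
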