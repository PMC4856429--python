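"""Relief-aware habitat quality on a small synthetic landscape.

Derives the terrain cost surface (slope-corrected distances plus curvature
barriers), propagates each threat class over it by cost distance, and maps
degradation and habitat quality.
"""

from ecoserv import (
    LandscapeSpec,
    derive_terrain,
    generate_landscape,
    run_habitat_model,
)

land = generate_landscape(LandscapeSpec(n_rows=150, n_cols=150, seed=7))
terrain = derive_terrain(land.dem)
print(f"slope: mean {terrain.slope_deg.mean():.1f} deg, max {terrain.slope_deg.max():.1f} deg")
print(f"barrier cells: {(terrain.mcr.values > 0).sum()} "
      f"({(terrain.mcr.values > 0).mean():.0%} of cells, the top-curvature quantile)")

quality, degradation, layers, beta = run_habitat_model(
    land.lulc, terrain.cost_surface, land.protected, land.lulc_table
)
print(f"\nthreat classes propagated: {[t.class_code for t in layers]}")
print(f"degradation D: mean {degradation.mean():.3f} (0 = pristine, 1 = saturated)")
print(f"habitat quality Q: mean {quality.mean():.2f}, max {quality.max():.2f}")
hab = quality.values[quality.values > 0]
print(f"on habitat cells only: mean Q {hab.mean():.2f}")
# Q is 0 on every threat cell by definition; on habitat it declines toward
# threat sources with the ~5%-at-d_max exponential decay, and protected
# cells are buffered by the accessibility factor.
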