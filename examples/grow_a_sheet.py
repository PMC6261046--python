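"""Grow cortical sheets along different spatiotemporal layouts.

Builds three growth layouts, replays their growth events and prints the
final geometry. The realistic layout interleaves low-density (early) and
high-density (late) areas around two origins; the inverse layout reverses
the density gradient; the 2D layout grows square rings around each origin.
"""

import corticodev as cd

for abbr in ("1D-1row-2or", "inverse-1D-1row-2or", "2D-2or"):
    layout = cd.get_layout(abbr)
    sheet = cd.build_final_sheet(layout, 0)
    dens = sheet.densities()
    print(f"{abbr}:")
    print(f"  {sheet.n_areas} areas of side {layout.area_side}, "
          f"{sheet.total_neurons()} neurons")
    print(f"  density range {dens.min():.0f}-{dens.max():.0f} neurons/unit^2 "
          f"({layout.n_tiers} tiers, {layout.density_fold:.0f}-fold span)")
    print(f"  growth events at steps "
          f"{cd.schedule_growth_events(layout).event_times}")

# The number of areas and the tier structure are fixed by the layout's
# growth mode, origin count and event count; densities ramp linearly
# across tiers between density_min and density_fold * density_min.
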