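"""Morphometry on vector smear scenes with known ground truth.

A scene describes one 100X microscope field: cell outlines (µm), nucleus
outlines, and cell-aggregate outlines. Measuring three fields yields one
slide read-out: mean complete-cell count, mean aggregate area, and — for
sparse smears only — the superficial cell index (SCI).
"""

from smearshed import count_complete_cells, measure_slide, polygon_area
from smearshed.cohort import generate_preset_scene, generate_scene

# a sparse, mixed-maturity smear, typical of asymptomatic BV
scenes = [generate_scene(n_complete=30, n_straddling=4,
                         class_mix=(0.4, 0.35, 0.25),
                         aggregate_area_um2=7_000.0, seed=s)
          for s in (1, 2, 3)]
for i, sc in enumerate(scenes, 1):
    print(f"field {i}: {count_complete_cells(sc)} complete cells of {len(sc.cells)} "
          f"(the rest straddle the image edge), "
          f"aggregate {polygon_area(sc.aggregate_outlines[0]):,.0f} um2")

m = measure_slide(scenes)
print(f"\nslide: mean count {m.mean_cell_count:.1f}/100X field, "
      f"mean aggregate {m.mean_aggregate_area_um2:,.0f} um2")
print(f"SCI = {m.n_superficial}/{m.n_total} = {m.sci:.3f}")
# SCI near 0.4: superficial cells depleted, immature cells exposed.

dense = [generate_preset_scene("fig1b", seed=s) for s in (4, 5, 6)]
md = measure_slide(dense)
print(f"\ndense symptomatic-BV-like slide: mean count {md.mean_cell_count:.0f}, "
      f"SCI scored: {md.sci is not None}")
# mean count > 50, so the slide is not eligible for SCI scoring.
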