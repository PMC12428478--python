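"""Render PMC surface sheets and the mean radar chart.

Each policy's nine dimension scores are arranged row-major into a 3x3 grid
and drawn as an interpolated 3-D sheet: concave regions mark weak
dimensions. The radar chart shows corpus-wide per-dimension means on nine
axes scaled [0, 1]. Files land in ./output/.
"""

from pathlib import Path

import pmcindex as px

out = Path("output")
out.mkdir(exist_ok=True)

schema = px.default_schema()
matrix, _ = px.reference_fixture()
results, means = px.score_corpus(matrix, schema)

best, worst = results[0], results[-1]
for r in (best, worst):
    path = px.render_surface(px.surface_matrix(r), out / f"surface_{r.code}.png")
    print(f"{r.code} (PMC {r.pmc_display:.2f}) surface -> {path}")

sheet = px.render_contact_sheet(results, out / "contact_sheet.png")
radar = px.render_radar(means, out / "radar.png", schema)
print(f"all 28 surfaces -> {sheet}")
print(f"mean radar chart -> {radar}")
# P22's sheet is nearly flat at 1 except the X2/X3 corner; P26's sheet is
# concave almost everywhere except the X7 (policy evaluation) corner.
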