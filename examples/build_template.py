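"""Build the ideal anterior-tooth template and export it.

The whole template is determined by one clinical measurement, the
central-incisor width.  Everything else follows from proportion rules:
width/height 80 %, regressive widths at 1/sqrt(2) per tooth, a 0.6 mm
lateral zenith drop, a 0.8 mm incisal step, and 50-40-30 connectors.
"""

from smilecurves import TemplateParams, build_template, render_svg, write_template_json

params = TemplateParams(central_width=8.0)
geom = build_template(params)

b = geom.boxes
print(f"central incisor box : {b[21].width:.3f} x {b[21].height:.3f} mm "
      f"(W/H = {100 * b[21].width / b[21].height:.1f} %)")
print(f"lateral incisor box : {b[22].width:.3f} mm wide "
      f"({100 * b[22].width / b[21].width:.1f} % of the central)")
print(f"canine box          : {b[23].width:.3f} mm wide "
      f"({100 * b[23].width / b[22].width:.1f} % of the lateral)")
print(f"lateral zenith drop : {b[22].y_zenith - b[21].y_zenith:.2f} mm")
print(f"incisal step        : {b[21].y_incisal - b[22].y_incisal:.2f} mm")
h1 = b[21].height
print("connector heights   : "
      + " / ".join(f"{100 * geom.connectors[p].height / h1:.0f}%"
                   for p in ("11-21", "21-22", "22-23"))
      + " of the central height (central-central / central-lateral / lateral-canine)")
print(f"total template width: {geom.total_width:.3f} mm")

with open("template.svg", "w") as fh:
    fh.write(render_svg(geom))           # 1 mm = 1 SVG user unit
write_template_json(geom, "template.json")
print("wrote template.svg and template.json")
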