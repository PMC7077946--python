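"""Register the template onto a photograph and render the overlay.

The registration needs only two designated points: the distal incisal
corners of the two central incisors (the combined central width), marked
on the photo.  A toy rendered 'photo' stands in for a real image so the
example is self-contained; with a real photograph, annotate the two
corners in pixel coordinates and build `dst` from them.
"""

from smilecurves import (
    DEFAULT_ANCHORS,
    OverlayStyle,
    build_template,
    fit_transform,
    ideal_landmarks,
    make_toy_image,
    render_overlay,
)

geom = build_template()
photo, true_transform = make_toy_image(geom, px_per_mm=12.0)
photo.save("toy_photo.png")

# pixel positions of the two anchor corners on the photo (here: computed
# from the toy image's known geometry; on a real photo, annotated by hand)
src = [ideal_landmarks(geom).points[name] for name in DEFAULT_ANCHORS]
dst = [true_transform.apply_point(p) for p in src]

transform = fit_transform(src, dst)
print(f"fitted transform: {transform.scale:.2f} px/mm, "
      f"rotation {transform.rotation:+.4f} rad, "
      f"translation ({transform.translation[0]:.1f}, {transform.translation[1]:.1f}) px")

render = render_overlay(
    geom,
    transform,
    image="toy_photo.png",
    style=OverlayStyle(opacity=0.5),
    out_path="overlay.png",
)
render.save("overlay.svg")
print(f"overlay canvas  : {render.image.size[0]} x {render.image.size[1]} px")
print("wrote overlay.png and overlay.svg")
# the semi-transparent boxes and reference lines now sit on the photo;
# any mismatch between template and teeth is read directly off the image
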