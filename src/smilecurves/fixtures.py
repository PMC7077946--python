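"""Synthetic smiles: ideal and deliberately deformed landmark sets.

Every deformation starts from the exact landmark export of the default
template and applies a documented, deterministic change, optionally
followed by i.i.d. isotropic Gaussian noise per landmark (seeded; seeds
are explicit arguments, never global state).  The presets emulate the
classic clinical presentations:

``ideal``
    the template itself, with lips placed for a medium lip line and a
    consonant smile arc (lower lip parallel to the incisal curve).
``gummy``
    upper lip raised above the zeniths by ``lift_mm`` (default 3.0),
    exposing gingiva: a high lip line.
``deep_bite``
    central incisal edges extended incisally by ``extension_mm``
    (default 1.5), the over-erupted centrals of a deep overbite.
``reverse_arc``
    the incisal outline mirrored about the lateral edge level, turning
    the soup plate into an inverted soup plate and the smile arc reverse.
``asymmetric``
    every patient-left landmark shifted ``shift_mm`` (default 1.0) along
    +x, breaking bilateral symmetry.
``flat_plate``
    all incisal edges levelled: flat-plate outline, flat smile arc.

These are geometric caricatures on a perfect grid: real photographs add
perspective, lip curvature variation, and annotation error far richer
than isotropic noise.
"""

from __future__ import annotations

from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .landmarks import LandmarkSet
from .template import TemplateGeometry, TemplateParams, build_template, ideal_landmarks

__all__ = ["make_smile", "make_toy_image", "PRESETS"]

Point = Tuple[float, float]


def _incisal_curve(params: TemplateParams) -> Tuple[float, float]:
    """Quadratic coefficients (a, c) of the ideal incisor incisal curve
    y = a x^2 + c through the central and lateral incisal midpoints."""
    w1, w2 = params.central_width, params.central_width * params.regressive_factor
    u_central = (w1 / 2.0) ** 2
    u_lateral = (w1 + w2 / 2.0) ** 2
    a = -params.incisal_step / (u_lateral - u_central)
    c = -a * u_central  # passes through the central edges at y = 0
    return a, c


def _make_lips(
    params: TemplateParams, lip_gap_mm: float, upper_lip_y: float
) -> Tuple[list, list]:
    half = params.central_width * (
        1 + params.regressive_factor + params.regressive_factor**2
    )
    a, c = _incisal_curve(params)
    xs = np.linspace(-1.1 * half, 1.1 * half, 11)
    lower = [(float(x), float(a * x**2 + c + lip_gap_mm)) for x in xs]
    upper = [(float(x), float(upper_lip_y)) for x in np.linspace(-1.1 * half, 1.1 * half, 9)]
    return upper, lower


def _deform_gummy(points, params, lift_mm: float = 3.0, **_):
    return points  # the lift acts on the upper lip, not the tooth landmarks


def _deform_deep_bite(points, params, extension_mm: float = 1.5, **_):
    out = dict(points)
    for t in (11, 21):
        for suffix in ("incisal_mid", "mesial_incisal", "distal_incisal"):
            x, y = out[f"{t}_{suffix}"]
            out[f"{t}_{suffix}"] = (x, y + extension_mm)
    return out


def _deform_reverse_arc(points, params, **_):
    y_lat = -params.incisal_step
    out = dict(points)
    for name, (x, y) in points.items():
        if name.endswith(("incisal_mid", "mesial_incisal", "distal_incisal")):
            out[name] = (x, 2.0 * y_lat - y)
    return out


def _deform_flat_plate(points, params, **_):
    out = dict(points)
    for name, (x, y) in points.items():
        if name.endswith(("incisal_mid", "mesial_incisal", "distal_incisal")):
            out[name] = (x, 0.0)
    return out


def _deform_asymmetric(points, params, shift_mm: float = 1.0, **_):
    out = {}
    for name, (x, y) in points.items():
        tokens = name.split("_")
        left = (
            tokens[0] in ("cp", "pap") and tokens[1][0] == "2" and tokens[2][0] == "2"
        ) or (tokens[0] not in ("cp", "pap") and tokens[0][0] == "2")
        out[name] = (x + shift_mm, y) if left else (x, y)
    return out


PRESETS: Dict[str, Callable] = {
    "ideal": lambda points, params, **_: points,
    "gummy": _deform_gummy,
    "deep_bite": _deform_deep_bite,
    "reverse_arc": _deform_reverse_arc,
    "asymmetric": _deform_asymmetric,
    "flat_plate": _deform_flat_plate,
}


def make_smile(
    preset: str = "ideal",
    noise_sd: float = 0.0,
    seed: int = 0,
    params: Optional[TemplateParams] = None,
    lip_gap_mm: float = 2.0,
    medium_lip_coverage: float = 0.10,
    **preset_kwargs,
) -> LandmarkSet:
    """Generate a synthetic landmark set in the template frame (mm).

    The tooth and connector landmarks of the ``ideal`` preset equal
    ``ideal_landmarks(build_template(params))`` exactly; lips are added
    so that the lip-line and smile-arc metrics are exercised (lower lip
    ``lip_gap_mm`` below and parallel to the incisal curve, upper lip
    covering ``medium_lip_coverage`` of the central crowns).  Gaussian
    noise of ``noise_sd`` mm is then added to every landmark and lip
    vertex.  Identical (preset, noise_sd, seed) give identical output.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    params = params or TemplateParams()
    geom = build_template(params)
    base = ideal_landmarks(geom)

    points = PRESETS[preset](dict(base.points), params, **preset_kwargs)

    h1 = params.central_height
    if preset == "gummy":
        lift = preset_kwargs.get("lift_mm", 3.0)
        upper_y = -h1 - lift
    else:
        upper_y = -h1 + medium_lip_coverage * h1
    upper, lower = _make_lips(params, lip_gap_mm, upper_y)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        points = {
            n: tuple(np.asarray(p) + rng.normal(0.0, noise_sd, 2))
            for n, p in points.items()
        }
        upper = [tuple(np.asarray(p) + rng.normal(0.0, noise_sd, 2)) for p in upper]
        lower = [tuple(np.asarray(p) + rng.normal(0.0, noise_sd, 2)) for p in lower]

    return LandmarkSet(
        frame="template",
        units="mm",
        points=points,
        upper_lip=upper,
        lower_lip=lower,
    )


def make_toy_image(
    geom: Optional[TemplateGeometry] = None,
    px_per_mm: float = 10.0,
    margin_mm: float = 5.0,
):
    """Render a toy 'photograph': white tooth boxes on a gum-pink field.

    Returns ``(image, transform)`` where the transform maps template mm
    to the image's pixels — enough to exercise overlay registration and
    rendering without any real photo.
    """
    from PIL import Image, ImageDraw

    from .registration import SimilarityTransform

    geom = geom or build_template()
    xs = [b.x_left for b in geom.boxes.values()] + [b.x_right for b in geom.boxes.values()]
    ys = [b.y_zenith for b in geom.boxes.values()] + [b.y_incisal for b in geom.boxes.values()]
    x0, y0 = min(xs) - margin_mm, min(ys) - margin_mm
    width = int(np.ceil((max(xs) - x0 + margin_mm) * px_per_mm))
    height = int(np.ceil((max(ys) - y0 + margin_mm) * px_per_mm))
    transform = SimilarityTransform(
        scale=px_per_mm, rotation=0.0, translation=(-x0 * px_per_mm, -y0 * px_per_mm)
    )
    img = Image.new("RGB", (width, height), (214, 136, 133))
    draw = ImageDraw.Draw(img)
    for box in geom.boxes.values():
        p0 = transform.apply_point((box.x_left, box.y_zenith))
        p1 = transform.apply_point((box.x_right, box.y_incisal))
        draw.rectangle([p0, p1], fill=(245, 242, 230), outline=(120, 100, 90))
    return img, transform
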