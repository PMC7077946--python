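"""Similarity-transform registration of the template onto a photograph.

The template is anchored to a photo by making the combined width of the
two central incisors coincide with the same span on the image: two
template points (by default the distal incisal corners of teeth 11 and
21) and their two designated pixel positions determine a unique
similarity transform (uniform scale + rotation + translation, no
reflection), computed in closed form via complex arithmetic.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = ["SimilarityTransform", "fit_transform", "DEFAULT_ANCHORS"]

Point = Tuple[float, float]

#: Default template-frame anchor landmarks: distal incisal corners of the
#: central incisors (the combined central-incisor width).
DEFAULT_ANCHORS: Tuple[str, str] = ("11_distal_incisal", "21_distal_incisal")


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s R(theta) x + t, mapping template mm to image pixels."""

    scale: float              # px per mm
    rotation: float           # radians, counter-clockwise in the y-down frame
    translation: Tuple[float, float]

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """2x3 affine matrix [sR | t]."""
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
            ]
        )

    def apply(self, points: Iterable[Point]) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix
        return pts @ m[:, :2].T + m[:, 2]

    def apply_point(self, point: Point) -> Point:
        x, y = self.apply([point])[0]
        return (float(x), float(y))

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = self.translation
        return SimilarityTransform(
            scale=inv_scale,
            rotation=-self.rotation,
            translation=(
                -inv_scale * (c * tx - s * ty),
                -inv_scale * (s * tx + c * ty),
            ),
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        rot = self.rotation + other.rotation
        t = self.apply_point(other.translation)
        return SimilarityTransform(self.scale * other.scale, rot, t)


def fit_transform(src_pair: Sequence[Point], dst_pair: Sequence[Point]) -> SimilarityTransform:
    """Unique similarity (no reflection) mapping two source points exactly
    onto two destination points.

    Closed form: with points as complex numbers, z' = sigma z + tau where
    sigma = (q2 - q1)/(p2 - p1); scale = |sigma|, rotation = arg(sigma).

    Raises ``ValueError`` when either pair is (numerically) coincident.
    """
    (p1, p2), (q1, q2) = src_pair, dst_pair
    zp1, zp2 = complex(*p1), complex(*p2)
    zq1, zq2 = complex(*q1), complex(*q2)
    if zp1 == zp2:
        raise ValueError("degenerate fit: source anchor points coincide")
    if zq1 == zq2:
        raise ValueError("degenerate fit: destination anchor points coincide")
    sigma = (zq2 - zq1) / (zp2 - zp1)
    tau = zq1 - sigma * zp1
    return SimilarityTransform(
        scale=abs(sigma),
        rotation=cmath.phase(sigma),
        translation=(tau.real, tau.imag),
    )
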