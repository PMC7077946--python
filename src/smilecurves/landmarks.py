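"""Landmark annotation schema for frontal smile photographs.

A :class:`LandmarkSet` holds named 2D anatomical points annotated on one
photograph (or expressed in the template's own millimetre frame).  The
name dictionary is fixed:

* per tooth ``t`` in {13, 12, 11, 21, 22, 23} (FDI notation):
  ``t_zenith``, ``t_incisal_mid``, ``t_mesial_incisal``, ``t_distal_incisal``;
* contact points: ``cp_11_21``, ``cp_11_12``, ``cp_21_22``, ``cp_12_13``,
  ``cp_22_23``;
* papilla tips: ``pap_11_21``, ``pap_11_12``, ``pap_21_22``, ``pap_12_13``,
  ``pap_22_23``;

plus two optional lip polylines (lower border of the upper lip, upper
border of the lower lip), each with at least three vertices.

Two file dialects are supported: a JSON document (one object per set) and
a tabular CSV/TSV file with a ``name,x,y`` header, where lip vertices are
encoded as ``upper_lip[i]`` / ``lower_lip[i]`` rows.  Coordinates are the
continuous positions of the anatomical points; no half-pixel centre
offset is applied (annotation tools differ on this; pick one and stay
consistent).  Pixel frames are y-down.

Partial sets are valid: metrics that lack their required landmarks are
reported absent rather than fabricated.  The only pairing rule is that a
tooth's mesial and distal incisal corners must be annotated together.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .template import TOOTH_IDS, CONNECTOR_PAIRS

__all__ = [
    "LandmarkSet",
    "LANDMARK_NAMES",
    "read_landmarks",
    "write_landmarks",
    "mirror_name",
]

_TOOTH_SUFFIXES = ("zenith", "incisal_mid", "mesial_incisal", "distal_incisal")

#: The full fixed dictionary of 34 point names (24 tooth points + 10 connector).
LANDMARK_NAMES: Tuple[str, ...] = tuple(
    f"{t}_{suffix}" for t in TOOTH_IDS for suffix in _TOOTH_SUFFIXES
) + tuple(
    f"{kind}_{pair.replace('-', '_')}"
    for kind in ("cp", "pap")
    for pair in CONNECTOR_PAIRS
)

_VALID_NAMES = frozenset(LANDMARK_NAMES)

_FRAME_UNITS = {"pixel": "px", "template": "mm"}

Point = Tuple[float, float]


def mirror_name(name: str) -> str:
    """Name of the landmark's bilateral partner (quadrant 1 <-> 2).

    Midline landmarks (``cp_11_21``, ``pap_11_21``) map to themselves.
    """
    if name.endswith("_11_21"):
        return name
    out = []
    for token in name.split("_"):
        if len(token) == 2 and token.isdigit() and token[0] in "12":
            quadrant = "2" if token[0] == "1" else "1"
            token = quadrant + token[1]
        out.append(token)
    # connector pairs are written mesial-first within a quadrant; re-sort
    if out[0] in ("cp", "pap"):
        a, b = sorted(out[1:], key=int)
        out = [out[0], str(a), str(b)]
    return "_".join(out)


class LandmarkSet(BaseModel):
    """Named anatomical points (+ lip polylines) for one photograph."""

    model_config = {"frozen": True}

    image_ref: Optional[str] = None
    frame: str = Field("pixel", pattern="^(pixel|template)$")
    units: str = Field("px", pattern="^(px|mm)$")
    points: Dict[str, Point] = Field(default_factory=dict)
    upper_lip: Optional[List[Point]] = None
    lower_lip: Optional[List[Point]] = None

    @field_validator("points")
    @classmethod
    def _known_finite(cls, v: Dict[str, Point]):
        for name, (x, y) in v.items():
            if name not in _VALID_NAMES:
                raise ValueError(f"unknown landmark name: {name!r}")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for landmark {name!r}")
        return v

    @field_validator("upper_lip", "lower_lip")
    @classmethod
    def _lip_ok(cls, v: Optional[List[Point]], info):
        if v is None:
            return v
        if len(v) < 3:
            raise ValueError(f"{info.field_name} polyline needs >= 3 points")
        for x, y in v:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate in {info.field_name}")
        return v

    @model_validator(mode="after")
    def _consistency(self):
        if _FRAME_UNITS[self.frame] != self.units:
            raise ValueError(
                f"frame {self.frame!r} requires units "
                f"{_FRAME_UNITS[self.frame]!r}, got {self.units!r}"
            )
        for t in TOOTH_IDS:
            mesial = f"{t}_mesial_incisal" in self.points
            distal = f"{t}_distal_incisal" in self.points
            if mesial != distal:
                raise ValueError(
                    f"tooth {t}: mesial and distal incisal corners must be "
                    "annotated together"
                )
        return self

    # -- convenience accessors -------------------------------------------

    def get(self, name: str) -> Optional[Point]:
        return self.points.get(name)

    def has(self, *names: str) -> bool:
        return all(n in self.points for n in names)

    def replace_points(self, **updates: Point) -> "LandmarkSet":
        """Copy with some named points replaced (validation re-run)."""
        pts = dict(self.points)
        pts.update(updates)
        return self.model_copy(update={"points": pts})


# ---------------------------------------------------------------------------
# file I/O


def write_landmarks(ls: LandmarkSet, path: str | Path) -> None:
    """Write a landmark set; dialect chosen by extension.

    ``.json`` writes the JSON document dialect; ``.csv`` / ``.tsv`` write
    the tabular ``name,x,y`` dialect.  Floats survive a round trip exactly
    (shortest-repr decimal serialization in both dialects).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        doc = {
            "format": "smilecurves-landmarks",
            "image_ref": ls.image_ref,
            "frame": ls.frame,
            "units": ls.units,
            "points": {name: list(p) for name, p in ls.points.items()},
            "upper_lip": [list(p) for p in ls.upper_lip] if ls.upper_lip else None,
            "lower_lip": [list(p) for p in ls.lower_lip] if ls.lower_lip else None,
        }
        path.write_text(json.dumps(doc, indent=2))
    elif suffix in (".csv", ".tsv"):
        sep = "\t" if suffix == ".tsv" else ","
        rows = [(name, x, y) for name, (x, y) in ls.points.items()]
        for attr in ("upper_lip", "lower_lip"):
            poly = getattr(ls, attr)
            if poly:
                rows.extend((f"{attr}[{i}]", x, y) for i, (x, y) in enumerate(poly))
        with path.open("w") as fh:
            fh.write(sep.join(("name", "x", "y")) + "\n")
            fh.write(f"# frame={ls.frame} units={ls.units}")
            if ls.image_ref:
                fh.write(f" image_ref={ls.image_ref}")
            fh.write("\n")
            for name, x, y in rows:
                fh.write(sep.join((name, repr(float(x)), repr(float(y)))) + "\n")
    else:
        raise ValueError(f"unsupported landmark file extension: {path.suffix!r}")


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read and validate a landmark file (JSON or tabular dialect).

    Raises ``ValueError`` on parse errors, unknown or duplicate landmark
    names, non-finite coordinates, or frame/units inconsistency; pydantic
    ``ValidationError`` messages name the offending landmark.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        doc = json.loads(text)
        if doc.get("format") not in (None, "smilecurves-landmarks"):
            raise ValueError(f"{path}: not a smilecurves landmark document")
        doc.pop("format", None)
        return LandmarkSet.model_validate(doc)
    return _read_tabular(path)


def _read_tabular(path: Path) -> LandmarkSet:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    meta: Dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().strip()
        body_lines = []
        for line in fh:
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
            else:
                body_lines.append(line)
    cols = [c.strip() for c in header.split(sep)]
    if cols[:3] != ["name", "x", "y"]:
        raise ValueError(f"{path}: expected 'name{sep}x{sep}y' header, got {header!r}")
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(body_lines)),
        sep=sep,
        names=cols,
        float_precision="round_trip",
    )

    points: Dict[str, Point] = {}
    lips: Dict[str, List[Tuple[int, Point]]] = {"upper_lip": [], "lower_lip": []}
    seen = set()
    for name, x, y in df.itertuples(index=False):
        name = str(name)
        if name in seen:
            raise ValueError(f"duplicate landmark name: {name!r}")
        seen.add(name)
        p = (float(x), float(y))
        if name.startswith(("upper_lip[", "lower_lip[")):
            attr, idx = name[:-1].split("[")
            lips[attr].append((int(idx), p))
        else:
            points[name] = p
    kwargs = {}
    for attr, verts in lips.items():
        if verts:
            kwargs[attr] = [p for _, p in sorted(verts)]
    return LandmarkSet(
        image_ref=meta.get("image_ref"),
        frame=meta.get("frame", "pixel"),
        units=meta.get("units", "px"),
        points=points,
        **kwargs,
    )
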