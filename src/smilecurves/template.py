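"""Parametric construction of the ideal anterior-tooth template.

The template models the six maxillary anterior teeth (canine to canine,
FDI 13..23) as rectangular "aesthetic boxes" in a millimetre frame, plus
the connector zones and the horizontal reference lines (cervical,
papillary, contact-point, incisal) that clinicians read off a frontal
smile photograph.

Coordinate convention (normative throughout the package): x increases to
the viewer's right, y increases *downward* (raster-image convention), the
origin sits on the midline at the level of the central-incisor incisal
edges.  The patient's right teeth (11, 12, 13) therefore occupy x < 0.

Construction rules encoded here:

* central incisor width/height ratio of 0.80 (8.0 mm wide -> 10.0 mm tall);
* regressive ("diagonal of the square") width proportion: each tooth's
  apparent width is 1/sqrt(2) of its mesial neighbour, i.e. the inverse
  ratio 1:1.414, commonly quoted as 71 %;
* gingival zeniths of centrals and canines level, lateral zeniths 0.6 mm
  below (more incisal);
* a 0.8 mm incisal step between central and lateral edges, canine tips
  level with the central edges, giving the "soup plate" incisal outline;
* connector zones obeying the 50-40-30 rule: connector height as a
  fraction of central-incisor height is 50 % between the centrals, 40 %
  between central and lateral, 30 % between lateral and canine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "TemplateParams",
    "ToothBox",
    "ConnectorZone",
    "TemplateGeometry",
    "build_template",
    "ideal_landmarks",
    "write_template_json",
    "read_template_json",
    "TOOTH_IDS",
    "CONNECTOR_PAIRS",
]

#: FDI tooth ids in viewer order, left (x most negative) to right.
TOOTH_IDS: Tuple[int, ...] = (13, 12, 11, 21, 22, 23)

#: Connector pair labels in viewer order.
CONNECTOR_PAIRS: Tuple[str, ...] = ("12-13", "11-12", "11-21", "21-22", "22-23")

_SQRT2_INV = 1.0 / math.sqrt(2.0)


class TemplateParams(BaseModel):
    """Scalar inputs and proportion constants that fully determine a template.

    All lengths are in millimetres.  Defaults reproduce the reference
    template built from an 8.0 mm central incisor.
    """

    model_config = {"frozen": True}

    central_width: float = Field(8.0, gt=0, description="central incisor width, mm")
    wh_ratio: float = Field(0.80, gt=0, le=1.0, description="central width/height")
    regressive_factor: float = Field(
        _SQRT2_INV, gt=0, lt=1.0, description="adjacent-width ratio (1/sqrt 2)"
    )
    lateral_zenith_drop: float = Field(
        0.6, ge=0, description="lateral zenith below central/canine zeniths, mm"
    )
    incisal_step: float = Field(
        0.8, ge=0, description="lateral incisal edge above central edge, mm"
    )
    connector_fractions: Tuple[float, float, float] = Field(
        (0.50, 0.40, 0.30),
        description="connector height / central height: central-central, "
        "central-lateral, lateral-canine",
    )
    papilla_line_fraction: float = Field(
        0.70,
        gt=0,
        lt=1.0,
        description="papilla-tip depth below the central zenith as a fraction "
        "of central height",
    )

    @field_validator("connector_fractions")
    @classmethod
    def _fractions_decreasing(cls, v: Tuple[float, float, float]):
        if not all(0.0 < f < 1.0 for f in v):
            raise ValueError("connector_fractions must each lie in (0, 1)")
        if not (v[0] > v[1] > v[2]):
            raise ValueError("connector_fractions must be strictly decreasing")
        return v

    @model_validator(mode="after")
    def _contacts_above_incisal(self):
        # contact point must stay gingival to the incisal edge
        if self.connector_fractions[0] >= self.papilla_line_fraction:
            raise ValueError(
                "papilla_line_fraction must exceed the largest connector "
                "fraction so contact points stay above the incisal edge"
            )
        return self

    @property
    def central_height(self) -> float:
        return self.central_width / self.wh_ratio


@dataclass(frozen=True)
class ToothBox:
    """Axis-aligned aesthetic box of one tooth in the template frame (mm)."""

    tooth_id: int
    x_mesial: float
    x_distal: float
    y_zenith: float
    y_incisal: float

    @property
    def width(self) -> float:
        return abs(self.x_distal - self.x_mesial)

    @property
    def height(self) -> float:
        return self.y_incisal - self.y_zenith

    @property
    def x_mid(self) -> float:
        return 0.5 * (self.x_mesial + self.x_distal)

    @property
    def x_left(self) -> float:
        return min(self.x_mesial, self.x_distal)

    @property
    def x_right(self) -> float:
        return max(self.x_mesial, self.x_distal)


@dataclass(frozen=True)
class ConnectorZone:
    """Connector zone between two adjacent teeth: the hang-glider shaped
    region bounded gingivally by the papilla tip and incisally by the
    contact point."""

    pair: str
    x: float
    y_papilla_tip: float
    y_contact_point: float

    @property
    def height(self) -> float:
        return self.y_contact_point - self.y_papilla_tip


@dataclass(frozen=True)
class TemplateGeometry:
    """Fully constructed template: six boxes, five connectors, reference lines.

    ``lines`` maps a line name (``cervical``, ``papillary``, ``contact``,
    ``incisal``) to a polyline of (x, y) vertices in viewer order.
    """

    params: TemplateParams
    boxes: Dict[int, ToothBox]
    connectors: Dict[str, ConnectorZone]
    lines: Dict[str, List[Tuple[float, float]]] = field(default_factory=dict)

    @property
    def total_width(self) -> float:
        return self.boxes[23].x_right - self.boxes[13].x_left

    def box(self, tooth_id: int) -> ToothBox:
        return self.boxes[tooth_id]


def build_template(params: TemplateParams | None = None) -> TemplateGeometry:
    """Construct the ideal template geometry from its parameters.

    Raises a pydantic ``ValidationError`` naming the offending field when
    the parameters are out of range.
    """
    if params is None:
        params = TemplateParams()
    elif not isinstance(params, TemplateParams):
        params = TemplateParams.model_validate(params)

    w1 = params.central_width
    h1 = params.central_height
    r = params.regressive_factor
    w2 = w1 * r
    w3 = w2 * r

    # Right half (patient left, quadrant 2): boxes abut with no gaps.
    spans = {
        21: (0.0, w1),
        22: (w1, w1 + w2),
        23: (w1 + w2, w1 + w2 + w3),
    }
    verticals = {
        # (y_zenith, y_incisal); canine tips level with central edges
        21: (-h1, 0.0),
        22: (-h1 + params.lateral_zenith_drop, -params.incisal_step),
        23: (-h1, 0.0),
    }

    boxes: Dict[int, ToothBox] = {}
    for tid, (x_mesial, x_distal) in spans.items():
        yz, yi = verticals[tid]
        boxes[tid] = ToothBox(tid, x_mesial, x_distal, yz, yi)
        mirror_id = tid - 10  # 21->11, 22->12, 23->13
        boxes[mirror_id] = ToothBox(mirror_id, -x_mesial, -x_distal, yz, yi)

    y_pap = -h1 * params.papilla_line_fraction
    f_cc, f_cl, f_lc = params.connector_fractions
    conn_defs = {
        "11-21": (0.0, f_cc),
        "21-22": (w1, f_cl),
        "11-12": (-w1, f_cl),
        "22-23": (w1 + w2, f_lc),
        "12-13": (-(w1 + w2), f_lc),
    }
    connectors = {
        pair: ConnectorZone(pair, x, y_pap, y_pap + f * h1)
        for pair, (x, f) in conn_defs.items()
    }

    order = TOOTH_IDS
    lines = {
        "cervical": [(boxes[t].x_mid, boxes[t].y_zenith) for t in order],
        "incisal": [(boxes[t].x_mid, boxes[t].y_incisal) for t in order],
        "papillary": [
            (connectors[p].x, connectors[p].y_papilla_tip) for p in CONNECTOR_PAIRS
        ],
        "contact": [
            (connectors[p].x, connectors[p].y_contact_point) for p in CONNECTOR_PAIRS
        ],
    }
    return TemplateGeometry(params=params, boxes=boxes, connectors=connectors, lines=lines)


def ideal_landmarks(geometry: TemplateGeometry):
    """Export the template's own landmark positions as a ``LandmarkSet``.

    Provides, per tooth: gingival zenith (box midline), incisal midpoint,
    and mesial/distal incisal corners; plus the five papilla tips and five
    contact points.  Frame is ``template``, units ``mm``.  Running the
    metric suite on this set reproduces every ideal classification with
    zero deviation.
    """
    from .landmarks import LandmarkSet  # local import to avoid a cycle

    points: Dict[str, Tuple[float, float]] = {}
    for tid, box in geometry.boxes.items():
        points[f"{tid}_zenith"] = (box.x_mid, box.y_zenith)
        points[f"{tid}_incisal_mid"] = (box.x_mid, box.y_incisal)
        points[f"{tid}_mesial_incisal"] = (box.x_mesial, box.y_incisal)
        points[f"{tid}_distal_incisal"] = (box.x_distal, box.y_incisal)
    for pair, conn in geometry.connectors.items():
        key = pair.replace("-", "_")
        points[f"pap_{key}"] = (conn.x, conn.y_papilla_tip)
        points[f"cp_{key}"] = (conn.x, conn.y_contact_point)

    return LandmarkSet(frame="template", units="mm", points=points)


# ---------------------------------------------------------------------------
# text serialization

def _geometry_to_dict(geometry: TemplateGeometry) -> dict:
    return {
        "format": "smilecurves-template",
        "units": "mm",
        "params": geometry.params.model_dump(),
        "boxes": {
            str(tid): {
                "x_mesial": b.x_mesial,
                "x_distal": b.x_distal,
                "y_zenith": b.y_zenith,
                "y_incisal": b.y_incisal,
            }
            for tid, b in sorted(geometry.boxes.items())
        },
        "connectors": {
            pair: {
                "x": c.x,
                "y_papilla_tip": c.y_papilla_tip,
                "y_contact_point": c.y_contact_point,
            }
            for pair, c in geometry.connectors.items()
        },
        "lines": {name: [list(p) for p in pts] for name, pts in geometry.lines.items()},
    }


def write_template_json(geometry: TemplateGeometry, path: str | Path) -> None:
    """Write a self-describing JSON document with params and all coordinates."""
    Path(path).write_text(json.dumps(_geometry_to_dict(geometry), indent=2))


def read_template_json(path: str | Path) -> TemplateGeometry:
    """Rebuild a geometry from its JSON export (via the stored params)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "smilecurves-template":
        raise ValueError(f"{path}: not a smilecurves template document")
    return build_template(TemplateParams.model_validate(doc["params"]))
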