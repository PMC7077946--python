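"""Smile-line and aesthetic-proportion metrics from landmark sets.

Implements the quantitative reading of a frontal smile photograph: the
six horizontal smile lines (upper lip, cervical, papillary, contact
point, incisal, lower lip), the regressive width proportions and central
width/height ratio, the 50-40-30 connector-zone ratios, a bilateral
symmetry score, and qualitative classifications (cervical line convex /
flat / concave; incisal outline soup plate / flat plate / inverted;
smile arc consonant / flat / reverse; lip line high / medium / low).

Orientation handling
--------------------
Photographs are rarely perfectly level, so any metric that reads a
vertical offset first canonicalizes in-plane rotation: the mean vector
from each patient-right landmark to its mirrored patient-left partner
defines the horizontal axis, and all coordinates are rotated so that it
is level.  On bilaterally symmetric input the estimated angle is exactly
zero.  This makes every metric invariant under global translation and
rotation of the landmark set.

Tolerances
----------
Class tolerances are stated in millimetres.  In a pixel frame they are
converted with the supplied mm-per-px scale when available; otherwise
they are scaled by the measured mean central-crown height relative to the
ideal crown height, which also makes class labels invariant under
uniform scaling of the landmark set.  Quantities that are *lengths* are
reported in mm only when the frame is ``template`` or a scale is given.

Metrics whose required landmarks are missing are reported as absent
(``None``) and flagged, never fabricated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .landmarks import LandmarkSet, mirror_name
from .template import TemplateParams

__all__ = [
    "MetricConfig",
    "SmileReport",
    "apparent_widths",
    "central_wh_ratios",
    "cervical_line_analysis",
    "incisal_outline",
    "connector_ratios",
    "papillary_contact_parallelism",
    "smile_arc",
    "lip_line",
    "symmetry_score",
    "full_report",
    "canonicalize_rotation",
]

#: patient-right / patient-left tooth triples (central, lateral, canine)
_SIDES = {"right": (11, 12, 13), "left": (21, 22, 23)}


@dataclass(frozen=True)
class MetricConfig:
    """Tunable thresholds for the qualitative classifications.

    The defaults are package conventions, configurable because the
    clinical definitions of the classes are qualitative.
    """

    line_tol_mm: float = 0.2          # cervical / incisal line class tolerance
    curvature_tol: float = 1e-3       # |a| below this (1/mm) counts as flat
    arc_ratio_range: Tuple[float, float] = (0.5, 2.0)
    lip_low_threshold: float = 0.25   # crown-coverage fraction above which lip is "low"
    include_canines_in_arc: bool = False
    ideal_central_height_mm: float = 10.0  # reference for scale-free tolerance


DEFAULT_CONFIG = MetricConfig()


# ---------------------------------------------------------------------------
# orientation + scale helpers


def _in_quadrant_1(name: str) -> bool:
    tokens = name.split("_")
    if tokens[0] in ("cp", "pap"):
        return tokens[1][0] == "1" and tokens[2][0] == "1"
    return tokens[0][0] == "1"


def _paired_names(ls: LandmarkSet) -> List[Tuple[str, str]]:
    """(patient-right name, patient-left name) for every mirrored pair
    present; midline landmarks excluded.  Each pair listed once, keyed by
    its quadrant-1 member."""
    pairs = []
    for name in ls.points:
        partner = mirror_name(name)
        if partner == name or partner not in ls.points:
            continue
        if _in_quadrant_1(name):
            pairs.append((name, partner))
    return pairs


def estimate_rotation(ls: LandmarkSet) -> float:
    """In-plane rotation (radians) of the dental arch relative to level,
    from the mean right-to-left mirrored-pair vector."""
    pairs = _paired_names(ls)
    if not pairs:
        return 0.0
    vx = vy = 0.0
    for right, left in pairs:
        (xr, yr), (xl, yl) = ls.points[right], ls.points[left]
        vx += xl - xr
        vy += yl - yr
    if vx == 0.0 and vy == 0.0:
        return 0.0
    return math.atan2(vy, vx)


def canonicalize_rotation(ls: LandmarkSet) -> LandmarkSet:
    """Rotate the set about the origin so the left-right axis is level."""
    theta = estimate_rotation(ls)
    if theta == 0.0:
        return ls
    c, s = math.cos(-theta), math.sin(-theta)

    def rot(p: Tuple[float, float]) -> Tuple[float, float]:
        x, y = p
        return (c * x - s * y, s * x + c * y)

    return ls.model_copy(
        update={
            "points": {n: rot(p) for n, p in ls.points.items()},
            "upper_lip": [rot(p) for p in ls.upper_lip] if ls.upper_lip else None,
            "lower_lip": [rot(p) for p in ls.lower_lip] if ls.lower_lip else None,
        }
    )


def _central_height(ls: LandmarkSet) -> Optional[float]:
    hs = []
    for t in (11, 21):
        z, m = ls.get(f"{t}_zenith"), ls.get(f"{t}_incisal_mid")
        if z is not None and m is not None and m[1] - z[1] > 0:
            hs.append(m[1] - z[1])
    return float(np.mean(hs)) if hs else None


def _units_per_mm(
    ls: LandmarkSet, mm_per_px: Optional[float], config: MetricConfig
) -> Tuple[float, bool]:
    """Input units per millimetre; second value says whether mm are known
    exactly (template frame or explicit scale) rather than inferred."""
    if ls.frame == "template":
        return 1.0, True
    if mm_per_px is not None:
        if mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        return 1.0 / mm_per_px, True
    h = _central_height(ls)
    if h is not None:
        return h / config.ideal_central_height_mm, False
    return 1.0, False


def _midline_x(ls: LandmarkSet) -> Optional[float]:
    cp = ls.get("cp_11_21")
    if cp is not None:
        return cp[0]
    pairs = _paired_names(ls)
    if not pairs:
        return None
    return float(
        np.mean([(ls.points[r][0] + ls.points[l][0]) / 2.0 for r, l in pairs])
    )


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class WidthsResult:
    widths: Dict[int, float]
    regressive_ratios: Dict[str, float]
    dominance_ok: Optional[bool]
    skipped: Tuple[int, ...] = ()


@dataclass(frozen=True)
class LineResult:
    """A per-side vertical-offset line classification (cervical/incisal)."""

    offsets: Dict[str, float]          # input units, y-down sign convention
    offsets_mm: Optional[Dict[str, float]]
    classification: str


@dataclass(frozen=True)
class ConnectorResult:
    percentages: Dict[str, float]      # of central incisor height
    reference_height: float
    flagged_pairs: Tuple[str, ...] = ()


@dataclass(frozen=True)
class ArcResult:
    classification: str
    a_incisal: float
    a_lip: Optional[float]
    delta_a: Optional[float]
    ratio: Optional[float]


@dataclass(frozen=True)
class LipLineResult:
    classification: str
    coverage: float                    # fraction of central crown covered
    display_mm: Optional[float]        # gingival display when lip above zeniths


@dataclass(frozen=True)
class SymmetryResult:
    score: float                       # input units
    score_mm: Optional[float]
    per_landmark: Dict[str, float]
    midline_x: float


@dataclass
class SmileReport:
    """Aggregate of every metric for one landmark set; absent metrics are
    ``None`` and explained in ``flags``."""

    frame: str
    units: str
    widths: Optional[WidthsResult] = None
    wh_ratio_central: Optional[Dict[int, float]] = None
    cervical_line: Optional[LineResult] = None
    incisal_outline: Optional[LineResult] = None
    papillary_contact_parallelism: Optional[float] = None
    connector_ratios: Optional[ConnectorResult] = None
    smile_arc: Optional[ArcResult] = None
    lip_line: Optional[LipLineResult] = None
    symmetry: Optional[SymmetryResult] = None
    dominance_ok: Optional[bool] = None
    deviations: Dict[str, float] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-metric table (``metric``, ``value`` columns)."""
        rows: List[Tuple[str, object]] = []

        def walk(prefix: str, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                if obj:
                    rows.append((prefix, ";".join(map(str, obj))))
            elif obj is not None:
                rows.append((prefix, obj))

        walk("", self.to_dict())
        return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# individual metrics


def apparent_widths(ls: LandmarkSet) -> Optional[WidthsResult]:
    """Apparent mesiodistal width per tooth from its incisal corner pair,
    the regressive width ratios per side, and the dominance check
    (widths strictly decreasing from central to canine on both sides)."""
    widths: Dict[int, float] = {}
    skipped: List[int] = []
    for side in _SIDES.values():
        for t in side:
            m, d = ls.get(f"{t}_mesial_incisal"), ls.get(f"{t}_distal_incisal")
            if m is None or d is None:
                skipped.append(t)
                continue
            widths[t] = math.dist(m, d)
    if not widths:
        return None

    ratios: Dict[str, float] = {}
    for central, lateral, canine in _SIDES.values():
        if lateral in widths and central in widths and widths[central] > 0:
            ratios[f"{lateral}/{central}"] = widths[lateral] / widths[central]
        if canine in widths and lateral in widths and widths[lateral] > 0:
            ratios[f"{canine}/{lateral}"] = widths[canine] / widths[lateral]

    dominance: Optional[bool] = None
    if all(t in widths for triple in _SIDES.values() for t in triple):
        dominance = all(
            widths[c] > widths[l] > widths[k] for c, l, k in _SIDES.values()
        )
    return WidthsResult(widths, ratios, dominance, tuple(skipped))


def central_wh_ratios(ls: LandmarkSet) -> Optional[Dict[int, float]]:
    """Width/height ratio per central incisor (height from zenith to
    incisal midpoint, measured after rotation canonicalization)."""
    ls = canonicalize_rotation(ls)
    out: Dict[int, float] = {}
    for t in (11, 21):
        m, d = ls.get(f"{t}_mesial_incisal"), ls.get(f"{t}_distal_incisal")
        z, mid = ls.get(f"{t}_zenith"), ls.get(f"{t}_incisal_mid")
        if None in (m, d, z, mid):
            continue
        height = mid[1] - z[1]
        if height > 0:
            out[t] = math.dist(m, d) / height
    return out or None


def cervical_line_analysis(
    ls: LandmarkSet,
    tol_mm: Optional[float] = None,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> Optional[LineResult]:
    """Shape of the gingival line through the six zeniths.

    Per side the offset is y(lateral zenith) minus the midpoint of the
    central and canine zenith heights; with y increasing downward a
    positive offset means the lateral zenith sits more incisally, the
    ideal *convex* configuration.  Classified convex / concave when the
    offset exceeds the tolerance on every annotated side, flat otherwise.
    """
    tol_mm = config.line_tol_mm if tol_mm is None else tol_mm
    ls = canonicalize_rotation(ls)
    upm, mm_known = _units_per_mm(ls, mm_per_px, config)

    offsets: Dict[str, float] = {}
    for side, (central, lateral, canine) in _SIDES.items():
        zs = [ls.get(f"{t}_zenith") for t in (central, lateral, canine)]
        if any(z is None for z in zs):
            continue
        (zc, zl, zk) = zs
        offsets[side] = zl[1] - 0.5 * (zc[1] + zk[1])
    if not offsets:
        return None

    tol = tol_mm * upm
    if all(d > tol for d in offsets.values()):
        cls = "convex"
    elif all(d < -tol for d in offsets.values()):
        cls = "concave"
    else:
        cls = "flat"
    offsets_mm = {s: d / upm for s, d in offsets.items()} if mm_known else None
    return LineResult(offsets, offsets_mm, cls)


def incisal_outline(
    ls: LandmarkSet,
    tol_mm: Optional[float] = None,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> Optional[LineResult]:
    """Incisal edge outline: soup plate (centrals extend further
    incisally than laterals), flat plate, or inverted soup plate."""
    tol_mm = config.line_tol_mm if tol_mm is None else tol_mm
    ls = canonicalize_rotation(ls)
    upm, mm_known = _units_per_mm(ls, mm_per_px, config)

    offsets: Dict[str, float] = {}
    for side, (central, lateral, _) in _SIDES.items():
        c, l = ls.get(f"{central}_incisal_mid"), ls.get(f"{lateral}_incisal_mid")
        if c is None or l is None:
            continue
        offsets[side] = c[1] - l[1]  # positive: central further incisal
    if not offsets:
        return None

    s = float(np.mean(list(offsets.values())))
    tol = tol_mm * upm
    if s > tol:
        cls = "soup_plate"
    elif s < -tol:
        cls = "inverted_soup_plate"
    else:
        cls = "flat_plate"
    offsets_mm = {k: d / upm for k, d in offsets.items()} if mm_known else None
    return LineResult(offsets, offsets_mm, cls)


_PAIR_GROUPS = {
    "central_central": ("11_21",),
    "central_lateral": ("11_12", "21_22"),
    "lateral_canine": ("12_13", "22_23"),
}


def connector_ratios(ls: LandmarkSet) -> Optional[ConnectorResult]:
    """Connector-zone heights (papilla tip to contact point) as
    percentages of the central-incisor height — the 50-40-30 rule.

    Central-lateral and lateral-canine values are averaged across sides;
    the reference height is the mean of the two central crown heights.
    Non-positive connector heights are flagged as annotation errors and
    excluded.
    """
    ls = canonicalize_rotation(ls)
    href = _central_height(ls)
    if href is None:
        return None

    percentages: Dict[str, float] = {}
    flagged: List[str] = []
    for group, pairs in _PAIR_GROUPS.items():
        vals = []
        for pair in pairs:
            pap, cp = ls.get(f"pap_{pair}"), ls.get(f"cp_{pair}")
            if pap is None or cp is None:
                continue
            h = cp[1] - pap[1]
            if h <= 0:
                flagged.append(pair)
                continue
            vals.append(h)
        if vals:
            percentages[group] = 100.0 * float(np.mean(vals)) / href
    if not percentages and not flagged:
        return None
    return ConnectorResult(percentages, href, tuple(flagged))


def _fit_line_angle(points: np.ndarray) -> Optional[float]:
    """Slope angle (radians) of a least-squares line through >= 2 points."""
    if len(points) < 2 or np.ptp(points[:, 0]) == 0:
        return None
    slope = np.polyfit(points[:, 0], points[:, 1], 1)[0]
    return math.atan(slope)


def papillary_contact_parallelism(ls: LandmarkSet) -> Optional[float]:
    """Angle in degrees between the fitted papillary and contact-point
    lines (0 when parallel)."""
    ls = canonicalize_rotation(ls)
    pap = np.array([p for n, p in ls.points.items() if n.startswith("pap_")])
    cp = np.array([p for n, p in ls.points.items() if n.startswith("cp_")])
    if len(pap) < 2 or len(cp) < 2:
        return None
    a1, a2 = _fit_line_angle(pap), _fit_line_angle(cp)
    if a1 is None or a2 is None:
        return None
    return abs(math.degrees(a1 - a2))


def smile_arc(
    ls: LandmarkSet,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> Optional[ArcResult]:
    """Smile-arc consonance: quadratic curvature of the incisal edge
    curve versus the lower-lip curve.

    Both curves are fit as y = ax^2 + bx + c with x centred on the
    midline.  With y increasing downward, a natural smile curve opens
    toward the gingiva (a < 0).  Consonant when both curvatures share
    that sign and their ratio lies within ``config.arc_ratio_range``;
    reverse when the signs oppose; flat when the incisal curvature is
    below ``config.curvature_tol`` or much flatter than the lip.  The
    incisal fit uses the four incisor incisal midpoints (canine tips are
    parallax-confounded; include via ``config.include_canines_in_arc``).
    """
    ls = canonicalize_rotation(ls)
    teeth = (11, 21, 12, 22) + ((13, 23) if config.include_canines_in_arc else ())
    pts = [ls.get(f"{t}_incisal_mid") for t in teeth]
    pts = np.array([p for p in pts if p is not None])
    if len(pts) < 3 or ls.lower_lip is None:
        return None
    lip = np.array(ls.lower_lip)
    x0 = _midline_x(ls)
    if x0 is None:
        x0 = float(np.mean(pts[:, 0]))

    def quad_a(arr: np.ndarray) -> Optional[float]:
        x = arr[:, 0] - x0
        if len(np.unique(np.round(x, 12))) < 3:
            return None
        return float(np.polyfit(x, arr[:, 1], 2)[0])

    a_inc = quad_a(pts)
    a_lip = quad_a(lip)
    if a_inc is None:
        return ArcResult("undetermined", math.nan, a_lip, None, None)

    upm, _ = _units_per_mm(ls, mm_per_px, config)
    tol_a = config.curvature_tol / upm  # a has units 1/length
    eps = 1e-12 / upm

    delta = a_inc - a_lip if a_lip is not None else None
    ratio = a_inc / a_lip if a_lip is not None and abs(a_lip) > eps else None

    if abs(a_inc) < tol_a:
        cls = "flat"
    elif a_lip is not None and abs(a_lip) > eps and a_inc * a_lip < 0:
        cls = "reverse"
    elif (
        ratio is not None
        and a_inc < 0
        and config.arc_ratio_range[0] <= ratio <= config.arc_ratio_range[1]
    ):
        cls = "consonant"
    else:
        # same-direction but mismatched curvature (or indeterminate lip):
        # non-consonant without inversion
        cls = "flat"
    return ArcResult(cls, a_inc, a_lip, delta, ratio)


def lip_line(
    ls: LandmarkSet,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> Optional[LipLineResult]:
    """Upper-lip line class from crown coverage of the central incisors.

    Coverage c = (lip height - zenith)/(crown height), evaluated at each
    central incisor's x position and averaged.  c < 0 means gingiva is
    displayed (class *high*, with the display amount in mm when the
    scale is known); c above ``config.lip_low_threshold`` is *low*;
    boundaries fall to *medium*.
    """
    ls = canonicalize_rotation(ls)
    if ls.upper_lip is None:
        return None
    lip = np.array(sorted(ls.upper_lip, key=lambda p: p[0]))

    coverages, displays = [], []
    for t in (11, 21):
        z, mid = ls.get(f"{t}_zenith"), ls.get(f"{t}_incisal_mid")
        if z is None or mid is None:
            continue
        x = mid[0]
        if not (lip[0, 0] <= x <= lip[-1, 0]):
            continue  # lip polyline does not span this tooth
        y_lip = float(np.interp(x, lip[:, 0], lip[:, 1]))
        height = mid[1] - z[1]
        if height <= 0:
            continue
        coverages.append((y_lip - z[1]) / height)
        displays.append(z[1] - y_lip)
    if not coverages:
        return None

    c = float(np.mean(coverages))
    upm, mm_known = _units_per_mm(ls, mm_per_px, config)
    if c < 0:
        cls = "high"
        display_mm = float(np.mean(displays)) / upm if mm_known else None
    else:
        display_mm = None
        cls = "low" if c > config.lip_low_threshold else "medium"
    return LipLineResult(cls, c, display_mm)


def symmetry_score(
    ls: LandmarkSet,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> Optional[SymmetryResult]:
    """Mean mirrored-landmark discrepancy after midline alignment.

    The midline is the vertical through ``cp_11_21`` when annotated,
    else the mean mid-x of the mirrored pairs.  Each patient-left
    landmark is compared with the reflection of its patient-right
    partner; 0 means perfect bilateral symmetry.
    """
    ls = canonicalize_rotation(ls)
    pairs = _paired_names(ls)
    if not pairs:
        return None
    x0 = _midline_x(ls)
    per: Dict[str, float] = {}
    for right, left in pairs:
        xr, yr = ls.points[right]
        xl, yl = ls.points[left]
        per[right] = math.dist((2.0 * x0 - xr, yr), (xl, yl))
    score = float(np.mean(list(per.values())))
    upm, mm_known = _units_per_mm(ls, mm_per_px, config)
    return SymmetryResult(score, score / upm if mm_known else None, per, x0)


# ---------------------------------------------------------------------------
# aggregate report


def full_report(
    ls: LandmarkSet,
    params: Optional[TemplateParams] = None,
    mm_per_px: Optional[float] = None,
    config: MetricConfig = DEFAULT_CONFIG,
) -> SmileReport:
    """Run every metric on a landmark set and, when template parameters
    are supplied, attach signed deviations from the ideal values.

    Sparse inputs produce sparse reports: metrics lacking landmarks are
    absent and flagged, never errors.
    """
    ls = canonicalize_rotation(ls)
    report = SmileReport(frame=ls.frame, units=ls.units)

    report.widths = apparent_widths(ls)
    if report.widths is not None:
        report.dominance_ok = report.widths.dominance_ok
        if report.widths.skipped:
            report.flags.append(
                "widths: missing incisal corners for teeth "
                + ",".join(map(str, report.widths.skipped))
            )
    else:
        report.flags.append("widths: no incisal corner pairs annotated")

    report.wh_ratio_central = central_wh_ratios(ls)
    if report.wh_ratio_central is None:
        report.flags.append("wh_ratio: central incisor landmarks incomplete")

    report.cervical_line = cervical_line_analysis(ls, None, mm_per_px, config)
    if report.cervical_line is None:
        report.flags.append("cervical_line: zeniths incomplete")
    elif len(report.cervical_line.offsets) < 2:
        report.flags.append("cervical_line: only one side annotated")

    report.incisal_outline = incisal_outline(ls, None, mm_per_px, config)
    if report.incisal_outline is None:
        report.flags.append("incisal_outline: incisal midpoints incomplete")

    report.papillary_contact_parallelism = papillary_contact_parallelism(ls)
    report.connector_ratios = connector_ratios(ls)
    if report.connector_ratios is None:
        report.flags.append("connector_ratios: papillae/contacts or central height missing")
    elif report.connector_ratios.flagged_pairs:
        report.flags.append(
            "connector_ratios: non-positive connector height (annotation error) for "
            + ",".join(report.connector_ratios.flagged_pairs)
        )

    report.smile_arc = smile_arc(ls, mm_per_px, config)
    if report.smile_arc is None:
        report.flags.append("smile_arc: needs >=3 incisal points and a lower-lip polyline")

    report.lip_line = lip_line(ls, mm_per_px, config)
    if report.lip_line is None:
        report.flags.append("lip_line: needs upper lip spanning the central incisors")

    report.symmetry = symmetry_score(ls, mm_per_px, config)
    if report.symmetry is None:
        report.flags.append("symmetry: no mirrored landmark pairs")

    if params is not None:
        _attach_deviations(report, params, ls, mm_per_px, config)
    return report


def _attach_deviations(
    report: SmileReport,
    params: TemplateParams,
    ls: LandmarkSet,
    mm_per_px: Optional[float],
    config: MetricConfig,
) -> None:
    dev = report.deviations
    r = params.regressive_factor
    if report.widths is not None:
        ratios = report.widths.regressive_ratios
        lat = [v for k, v in ratios.items() if k.split("/")[0] in ("12", "22")]
        can = [v for k, v in ratios.items() if k.split("/")[0] in ("13", "23")]
        if lat:
            dev["regressive_lateral"] = float(np.mean(lat)) - r
        if can:
            dev["regressive_canine"] = float(np.mean(can)) - r
    if report.wh_ratio_central:
        dev["wh_ratio"] = (
            float(np.mean(list(report.wh_ratio_central.values()))) - params.wh_ratio
        )
    if report.connector_ratios is not None:
        ideal = dict(
            zip(
                ("central_central", "central_lateral", "lateral_canine"),
                params.connector_fractions,
            )
        )
        for group, pct in report.connector_ratios.percentages.items():
            dev[f"connector_{group}_pct"] = pct - 100.0 * ideal[group]

    _, mm_known = _units_per_mm(ls, mm_per_px, config)
    if mm_known:
        if report.cervical_line is not None and report.cervical_line.offsets_mm:
            dev["zenith_drop_mm"] = (
                float(np.mean(list(report.cervical_line.offsets_mm.values())))
                - params.lateral_zenith_drop
            )
        if report.incisal_outline is not None and report.incisal_outline.offsets_mm:
            dev["incisal_step_mm"] = (
                float(np.mean(list(report.incisal_outline.offsets_mm.values())))
                - params.incisal_step
            )
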