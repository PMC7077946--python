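"""Smile-line metrics: derived oracles, classifications, invariances."""

import math

import numpy as np
import pytest

from smilecurves import (
    LandmarkSet,
    TemplateParams,
    apparent_widths,
    cervical_line_analysis,
    central_wh_ratios,
    connector_ratios,
    full_report,
    incisal_outline,
    lip_line,
    make_smile,
    papillary_contact_parallelism,
    smile_arc,
    symmetry_score,
)
from smilecurves.landmarks import mirror_name

SQRT2_INV = 1.0 / math.sqrt(2.0)


def transformed(ls: LandmarkSet, angle=0.0, dx=0.0, dy=0.0, scale=1.0) -> LandmarkSet:
    """Apply a global similarity to every coordinate of a landmark set."""
    c, s = math.cos(angle), math.sin(angle)

    def f(p):
        x, y = p
        return (scale * (c * x - s * y) + dx, scale * (s * x + c * y) + dy)

    return ls.model_copy(
        update={
            "points": {n: f(p) for n, p in ls.points.items()},
            "upper_lip": [f(p) for p in ls.upper_lip] if ls.upper_lip else None,
            "lower_lip": [f(p) for p in ls.lower_lip] if ls.lower_lip else None,
        }
    )


def reflected(ls: LandmarkSet, x0: float) -> LandmarkSet:
    """Mirror a landmark set across the vertical line x = x0, swapping sides."""

    def f(p):
        return (2.0 * x0 - p[0], p[1])

    return ls.model_copy(
        update={
            "points": {mirror_name(n): f(p) for n, p in ls.points.items()},
            "upper_lip": [f(p) for p in ls.upper_lip] if ls.upper_lip else None,
            "lower_lip": [f(p) for p in ls.lower_lip] if ls.lower_lip else None,
        }
    )


class TestApparentWidths:
    def test_ideal_ratios_are_inverse_sqrt2(self, ideal_ls):
        res = apparent_widths(ideal_ls)
        for v in res.regressive_ratios.values():
            assert v == pytest.approx(SQRT2_INV, abs=1e-9)
        assert res.dominance_ok is True

    def test_equal_widths_break_dominance(self, ideal_ls):
        pts = dict(ideal_ls.points)
        for t in (13, 12, 11, 21, 22, 23):
            x0 = pts[f"{t}_mesial_incisal"][0]
            y = pts[f"{t}_mesial_incisal"][1]
            sign = 1.0 if pts[f"{t}_distal_incisal"][0] > x0 else -1.0
            pts[f"{t}_distal_incisal"] = (x0 + sign * 8.0, y)
        res = apparent_widths(ideal_ls.model_copy(update={"points": pts}))
        assert all(v == pytest.approx(1.0) for v in res.regressive_ratios.values())
        assert res.dominance_ok is False

    def test_printed_width_triplet(self):
        # widths 8.0 / 5.657 / 4.0: canine/lateral = 0.7072 to 4 dp
        pts = {}
        for t, (x, w) in {11: (-8.0, 8.0), 12: (-13.657, 5.657), 13: (-17.657, 4.0)}.items():
            pts[f"{t}_mesial_incisal"] = (x + w, 0.0)
            pts[f"{t}_distal_incisal"] = (x, 0.0)
        res = apparent_widths(LandmarkSet(points=pts))
        assert round(res.regressive_ratios["13/12"], 4) == 0.7071  # 4.0/5.657
        assert res.dominance_ok is None  # left side absent

    def test_missing_corners_skip_tooth(self, ideal_ls):
        pts = {n: p for n, p in ideal_ls.points.items() if not n.startswith("13_")}
        res = apparent_widths(ideal_ls.model_copy(update={"points": pts}))
        assert 13 in res.skipped and 13 not in res.widths


class TestCervicalLine:
    def test_ideal_is_convex_with_point_six_offset(self, ideal_ls):
        res = cervical_line_analysis(ideal_ls)
        assert res.classification == "convex"
        assert res.offsets["right"] == pytest.approx(0.6, abs=1e-9)
        assert res.offsets["left"] == pytest.approx(0.6, abs=1e-9)

    def test_level_zeniths_are_flat(self, ideal_ls):
        pts = dict(ideal_ls.points)
        for t in (13, 12, 11, 21, 22, 23):
            x, _ = pts[f"{t}_zenith"]
            pts[f"{t}_zenith"] = (x, -10.0)
        res = cervical_line_analysis(ideal_ls.model_copy(update={"points": pts}))
        assert res.classification == "flat"

    def test_raised_lateral_zeniths_are_concave(self, ideal_ls):
        pts = dict(ideal_ls.points)
        for t in (12, 22):
            x, _ = pts[f"{t}_zenith"]
            pts[f"{t}_zenith"] = (x, -11.0)  # 1.0 mm apical of the central/canine line
        res = cervical_line_analysis(ideal_ls.model_copy(update={"points": pts}))
        assert res.classification == "concave"
        assert res.offsets["left"] == pytest.approx(-1.0)


class TestIncisalOutline:
    def test_ideal_is_soup_plate(self, ideal_ls):
        res = incisal_outline(ideal_ls)
        assert res.classification == "soup_plate"
        assert res.offsets["right"] == pytest.approx(0.8, abs=1e-9)

    def test_level_edges_are_flat_plate(self):
        res = incisal_outline(make_smile("flat_plate"))
        assert res.classification == "flat_plate"

    def test_short_centrals_are_inverted(self, ideal_ls):
        pts = dict(ideal_ls.points)
        for t in (11, 21):
            x, y = pts[f"{t}_incisal_mid"]
            pts[f"{t}_incisal_mid"] = (x, y - 1.8)  # centrals 1.0 mm short of laterals
        res = incisal_outline(ideal_ls.model_copy(update={"points": pts}))
        assert res.classification == "inverted_soup_plate"


class TestConnectorRatios:
    def test_ideal_recovers_50_40_30(self, ideal_ls):
        res = connector_ratios(ideal_ls)
        assert res.percentages["central_central"] == pytest.approx(50.0, abs=1e-9)
        assert res.percentages["central_lateral"] == pytest.approx(40.0, abs=1e-9)
        assert res.percentages["lateral_canine"] == pytest.approx(30.0, abs=1e-9)
        assert res.reference_height == pytest.approx(10.0)

    def test_hand_built_5_4_3_over_height_10(self):
        pts = {
            "11_zenith": (-4.0, -10.0),
            "11_incisal_mid": (-4.0, 0.0),
            "21_zenith": (4.0, -10.0),
            "21_incisal_mid": (4.0, 0.0),
            "pap_11_21": (0.0, -7.0), "cp_11_21": (0.0, -2.0),
            "pap_21_22": (8.0, -7.0), "cp_21_22": (8.0, -3.0),
            "pap_22_23": (13.0, -7.0), "cp_22_23": (13.0, -4.0),
        }
        res = connector_ratios(LandmarkSet(frame="template", units="mm", points=pts))
        assert res.percentages == pytest.approx(
            {"central_central": 50.0, "central_lateral": 40.0, "lateral_canine": 30.0}
        )

    def test_degenerate_connector_flagged(self, ideal_ls):
        ls = ideal_ls.replace_points(cp_11_21=ideal_ls.points["pap_11_21"])
        res = connector_ratios(ls)
        assert "11_21" in res.flagged_pairs
        assert "central_central" not in res.percentages


class TestSmileArc:
    def test_ideal_preset_is_consonant(self, ideal_smile):
        res = smile_arc(ideal_smile)
        assert res.classification == "consonant"
        assert res.ratio == pytest.approx(1.0, abs=1e-6)

    def test_level_incisal_points_are_flat(self):
        res = smile_arc(make_smile("flat_plate"))
        assert res.classification == "flat"

    def test_inverted_curvature_is_reverse(self):
        res = smile_arc(make_smile("reverse_arc"))
        assert res.classification == "reverse"
        assert res.a_incisal > 0 > res.a_lip

    def test_collinear_x_is_undetermined(self, ideal_smile):
        pts = {n: p for n, p in ideal_smile.points.items()}
        for t in (11, 12, 22):  # collapse three incisal mids onto one x
            pts[f"{t}_incisal_mid"] = (0.0, pts[f"{t}_incisal_mid"][1])
        pts.pop("21_incisal_mid")
        ls = ideal_smile.model_copy(update={"points": pts})
        assert smile_arc(ls).classification == "undetermined"

    def test_absent_without_lip(self, ideal_ls):
        assert smile_arc(ideal_ls) is None


class TestLipLine:
    def _with_upper_lip(self, ideal_ls, y):
        lip = [(-20.0, y), (0.0, y), (20.0, y)]
        return ideal_ls.model_copy(update={"upper_lip": lip})

    def test_lip_above_zeniths_is_high_with_display(self, ideal_ls):
        res = lip_line(self._with_upper_lip(ideal_ls, -12.0))
        assert res.classification == "high"
        assert res.display_mm == pytest.approx(2.0, abs=1e-9)

    def test_lip_exactly_at_zenith_is_medium(self, ideal_ls):
        res = lip_line(self._with_upper_lip(ideal_ls, -10.0))
        assert res.classification == "medium"
        assert res.coverage == pytest.approx(0.0, abs=1e-12)

    def test_lip_covering_30_percent_is_low(self, ideal_ls):
        res = lip_line(self._with_upper_lip(ideal_ls, -7.0))
        assert res.classification == "low"
        assert res.coverage == pytest.approx(0.30)

    def test_lip_not_spanning_teeth_is_absent(self, ideal_ls):
        lip = [(30.0, -9.0), (40.0, -9.0), (50.0, -9.0)]
        assert lip_line(ideal_ls.model_copy(update={"upper_lip": lip})) is None


class TestSymmetry:
    def test_ideal_template_is_exactly_symmetric(self, ideal_ls):
        assert symmetry_score(ideal_ls).score == 0.0

    def test_single_displaced_zenith_contributes_its_offset(self, ideal_ls):
        ls = ideal_ls.replace_points(
            **{"22_zenith": tuple(np.add(ideal_ls.points["22_zenith"], (1.0, 0.0)))}
        )
        res = symmetry_score(ls)
        n_pairs = len(res.per_landmark)
        assert n_pairs == 16
        assert res.per_landmark["12_zenith"] == pytest.approx(1.0)
        assert res.score == pytest.approx(1.0 / n_pairs)

    def test_one_sided_set_is_absent(self, ideal_ls):
        pts = {n: p for n, p in ideal_ls.points.items() if n.startswith(("21", "22", "23"))}
        assert symmetry_score(ideal_ls.model_copy(update={"points": pts})) is None


def test_papillary_contact_parallel_on_ideal(ideal_ls):
    # symmetric contact points fit a level line; papillae are level by design
    assert papillary_contact_parallelism(ideal_ls) == pytest.approx(0.0, abs=1e-9)


class TestFullReport:
    def test_ideal_self_consistency(self, ideal_smile, default_params):
        rep = full_report(ideal_smile, params=default_params)
        assert rep.deviations
        for key, value in rep.deviations.items():
            assert abs(value) < 1e-9, key
        assert rep.cervical_line.classification == "convex"
        assert rep.incisal_outline.classification == "soup_plate"
        assert rep.smile_arc.classification == "consonant"
        assert rep.dominance_ok is True

    def test_widened_lateral_flagged(self, ideal_ls, default_params):
        pts = dict(ideal_ls.points)
        for t in (12, 22):
            m, d = pts[f"{t}_mesial_incisal"], pts[f"{t}_distal_incisal"]
            sign = 1.0 if d[0] > m[0] else -1.0
            pts[f"{t}_distal_incisal"] = (m[0] + sign * 8.0, d[1])
        rep = full_report(ideal_ls.model_copy(update={"points": pts}), params=default_params)
        assert rep.dominance_ok is False
        assert rep.deviations["regressive_lateral"] == pytest.approx(1.0 - SQRT2_INV)

    def test_empty_set_reports_everything_absent(self):
        rep = full_report(LandmarkSet())
        assert rep.widths is None and rep.cervical_line is None
        assert rep.smile_arc is None and rep.symmetry is None
        assert rep.deviations == {} and rep.flags

    def test_report_exports(self, ideal_smile, default_params):
        rep = full_report(ideal_smile, params=default_params)
        d = rep.to_dict()
        assert d["cervical_line"]["classification"] == "convex"
        frame = rep.to_frame()
        assert {"metric", "value"} == set(frame.columns)
        assert (frame["metric"] == "incisal_outline.classification").any()


class TestInvariances:
    @pytest.mark.parametrize("angle,dx,dy", [(0.3, 40.0, -25.0), (-1.1, -7.5, 3.0)])
    def test_rotation_translation_invariance(self, ideal_smile, default_params, angle, dx, dy):
        base = full_report(ideal_smile, params=default_params)
        moved = full_report(transformed(ideal_smile, angle, dx, dy), params=default_params)
        assert moved.cervical_line.classification == "convex"
        assert moved.incisal_outline.classification == "soup_plate"
        assert moved.smile_arc.classification == "consonant"
        assert moved.lip_line.classification == base.lip_line.classification
        for key in base.deviations:
            assert moved.deviations[key] == pytest.approx(base.deviations[key], abs=1e-7)
        assert moved.symmetry.score == pytest.approx(base.symmetry.score, abs=1e-9)

    def test_uniform_scaling_preserves_ratios_and_classes(self, ideal_smile):
        # a pixel-frame annotation at an arbitrary unknown magnification
        scaled = transformed(ideal_smile, scale=17.0).model_copy(
            update={"frame": "pixel", "units": "px"}
        )
        rep = full_report(scaled)
        assert rep.cervical_line.classification == "convex"
        assert rep.incisal_outline.classification == "soup_plate"
        assert rep.smile_arc.classification == "consonant"
        assert rep.lip_line.classification == "medium"
        for v in rep.widths.regressive_ratios.values():
            assert v == pytest.approx(SQRT2_INV, abs=1e-9)
        assert rep.connector_ratios.percentages["central_central"] == pytest.approx(50.0)

    def test_mirror_invariance_swaps_sides(self, default_params):
        ls = make_smile("asymmetric")
        base = full_report(ls, params=default_params)
        mirrored = full_report(reflected(ls, x0=3.0), params=default_params)
        assert mirrored.symmetry.score == pytest.approx(base.symmetry.score, abs=1e-9)
        assert mirrored.incisal_outline.classification == base.incisal_outline.classification
        assert mirrored.cervical_line.offsets["left"] == pytest.approx(
            base.cervical_line.offsets["right"], abs=1e-9
        )
        assert mirrored.cervical_line.offsets["right"] == pytest.approx(
            base.cervical_line.offsets["left"], abs=1e-9
        )
        w_base = base.widths.widths
        w_mir = mirrored.widths.widths
        assert w_mir[12] == pytest.approx(w_base[22], abs=1e-9)
        assert w_mir[22] == pytest.approx(w_base[12], abs=1e-9)

    def test_scale_conversion_reports_mm(self, ideal_smile, default_params):
        px = transformed(ideal_smile, scale=20.0).model_copy(
            update={"frame": "pixel", "units": "px"}
        )
        rep = full_report(px, params=default_params, mm_per_px=0.05)
        assert rep.cervical_line.offsets_mm["right"] == pytest.approx(0.6, abs=1e-9)
        assert rep.deviations["incisal_step_mm"] == pytest.approx(0.0, abs=1e-9)
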