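# smilecurves

Quantitative smile-aesthetics analysis for orthodontic and restorative
planning: a parametric generator of the ideal anterior-tooth template, a
metric suite for landmark annotations of frontal smile photographs, and
an overlay renderer that registers the template onto a photo.

The package is for clinicians and researchers who evaluate the aesthetic
positioning of the six maxillary anterior teeth (FDI 13–23) from frontal
smile or intraoral photographs, and for tool builders who need those
references as code.

## The model

The whole ideal geometry follows from one measurement, the central
incisor width *W₁* (default 8.0 mm), plus classical proportion rules:

- **Dominance and regressive proportion.** Apparent widths decrease from
  the central incisor outward by the diagonal-of-the-square ratio:
  *W₂ = W₁/√2*, *W₃ = W₂/√2* (the inverse ratio 1:1.414, commonly quoted
  as 71 %).
- **Central proportion.** Width/height of the central incisor is 80 %:
  *H₁ = W₁/0.8*, so an 8.0 mm central is 10.0 mm tall.
- **Cervical line.** Gingival zeniths of centrals and canines are level;
  the lateral zenith sits 0.6 mm below them, giving a convex gingival
  line.
- **Incisal line.** A 0.8 mm step between central and lateral incisal
  edges, with canine tips level with the central edges: the "soup plate"
  outline.
- **Connector zones (50-40-30 rule).** The zone where adjacent teeth
  appear to touch — bounded by the papilla tip and the contact point —
  spans 50 % of the central incisor height between the centrals, 40 %
  between central and lateral, and 30 % between lateral and canine.

The metric suite reads the same references off a photograph's landmarks:
the six horizontal smile lines (upper lip, cervical, papillary, contact
point, incisal, lower lip), the regressive width ratios, connector
percentages, a bilateral symmetry score, and the qualitative classes
(lip line high/medium/low, cervical line convex/flat/concave, incisal
outline soup/flat/inverted plate, smile arc consonant/flat/reverse).
Registration onto a photo is a two-point similarity fit anchored on the
combined central-incisor width.

## Worked example

```python
from smilecurves import TemplateParams, build_template, full_report, make_smile

geom = build_template(TemplateParams(central_width=8.0))
b = geom.boxes
print(b[21].width, b[21].height)    # 8.0 10.0  (the 80 % central proportion)
print(round(b[22].width, 3))        # 5.657     (8.0 / sqrt 2)
print(round(b[23].width, 3))        # 4.0       (two regressive steps)

# score a synthetic "gummy smile" (upper lip 3 mm above the zeniths,
# 0.1 mm annotation noise) against the ideal template
ls = make_smile("gummy", lift_mm=3.0, noise_sd=0.1, seed=42)
report = full_report(ls, params=TemplateParams())
print(report.lip_line.classification, round(report.lip_line.display_mm, 2))
# high 2.89    -> gingiva is displayed; ~3 mm exposure recovered from noisy points
print(report.cervical_line.classification, report.incisal_outline.classification)
# convex soup_plate   -> the tooth geometry still matches the ideal template
print({k: round(v, 1) for k, v in report.connector_ratios.percentages.items()})
# {'central_central': 49.7, 'central_lateral': 38.9, 'lateral_canine': 29.3}
```

The report's `deviations` field gives the signed difference of each
measured quantity from its template value (all ≈ 0 here except the lip,
because only the lip was moved).  See `examples/` for runnable scripts
covering template export, photo analysis, overlay registration and the
synthetic presets, and `docs/methods.md` for the full model description.

## Command line

```bash
smilecurves template --central-width 8.0 --out template.svg --json template.json
smilecurves simulate --preset gummy --noise-sd 0.1 --seed 7 --out lm.json
smilecurves analyze --landmarks lm.json --out report.json
smilecurves overlay --image photo.jpg --landmarks lm.json --opacity 0.5 --out overlay.png
```

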