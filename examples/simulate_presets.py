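"""Generate the synthetic smile presets and show how the metrics react.

Each preset applies one documented deformation to the ideal template's
landmarks; the table shows which classification picks it up.
"""

from smilecurves import PRESETS, full_report, make_smile, write_landmarks

print(f"{'preset':<12} {'lip line':<8} {'cervical':<8} {'incisal':<20} "
      f"{'smile arc':<10} {'symmetry (mm)':>13}")
for preset in sorted(PRESETS):
    report = full_report(make_smile(preset, noise_sd=0.0))
    print(f"{preset:<12} "
          f"{report.lip_line.classification:<8} "
          f"{report.cervical_line.classification:<8} "
          f"{report.incisal_outline.classification:<20} "
          f"{report.smile_arc.classification:<10} "
          f"{report.symmetry.score:>13.3f}")

ls = make_smile("deep_bite", noise_sd=0.1, seed=7)
write_landmarks(ls, "deep_bite_noisy.json")
print("\nwrote deep_bite_noisy.json (0.1 mm noise, seed 7) — feed it to "
      "`smilecurves analyze --landmarks deep_bite_noisy.json`")
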