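"""Flexibility analytics on synthetic two-temperature ensembles.

Builds an ideal helix, perturbs it with Gaussian noise at a "low" and a
"high" temperature (the high one with a planted flexible stretch), and
runs the trajectory-style analytics: per-residue RMSF, the
RMSF-increase regions, hydrogen-bond counts and the representative
frame.
"""

import numpy as np

import thermoscreen as ts
from thermoscreen.synthetic import EnsembleSpec

helix = ts.make_helix(40)
flexible = range(18, 23)  # the stretch we make "melt" at high temperature

low = ts.make_ensemble(helix, EnsembleSpec(200, {}, 0.12, seed=1), 300)
high = ts.make_ensemble(
    helix, EnsembleSpec(200, {r: 0.55 for r in flexible}, 0.12, seed=2), 400)

prof_low = ts.per_residue_rmsf(low)
prof_high = ts.per_residue_rmsf(high)
print(f"mean RMSF at 300 K: {prof_low.as_array().mean():.3f} A")
print(f"mean RMSF at 400 K: {prof_high.as_array().mean():.3f} A "
      f"(driven by the planted stretch)")

regions = ts.rmsf_increase_regions(prof_low, prof_high,
                                   delta_min=0.5, min_len=3)
print(f"RMSF-increase regions (delta >= 0.5 A over >= 3 residues): "
      f"{[str(r) for r in regions]}")
print(f"planted stretch was residues {flexible.start}-{flexible.stop - 1}")

hb = ts.hbond_series(low)
print(f"hydrogen bonds per frame at 300 K: mean {hb.mean:.1f} "
      f"(ideal helix has n-4 = {len(helix) - 4} backbone bonds)")

rep = ts.representative_frame(low)
print(f"representative frame (closest to the average conformation): {rep}")
print("\nThe planted region is recovered exactly; on real trajectories "
      "the same call chain runs on a multi-model PDB via read_ensemble().")
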