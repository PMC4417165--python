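# mmdna

Structural analysis of mismatch-containing B-DNA duplexes, for people who
study how a mispaired base (G·T, A·A, C·C, ...) distorts the double helix
and how far that distortion travels.

A mismatched pair breaks Watson-Crick isomorphism: its hydrogen-bonding
pattern becomes labile, the pair "breathes" (transiently opens toward a
groove), local helical parameters shift, groove widths and the surrounding
cation atmosphere change, and small systematic deviations in mean geometry
can propagate several base-pair steps away from the lesion. `mmdna`
implements the measurement layer for all of this on ensembles of duplex
snapshots (multi-model PDB), together with a synthetic duplex builder and
ensemble generator that provides exact ground truth for every quantity the
analysers measure — so the whole pipeline is testable without microsecond
simulations.

## What it computes

- **Helical coordinates.** Base reference frames are fitted by least-squares
  superposition of idealized base geometries; pairs and steps are decomposed
  with a symmetric mid-frame (CEHS-style) scheme into the six intra-pair
  (shear, stretch, stagger / buckle, propeller, opening) and six step
  (shift, slide, rise / tilt, roll, twist) coordinates. The builder inverts
  the same scheme, so build→analyze is exact to numerical precision.
- **Glycosidic conformers.** χ = O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2
  (pyrimidines), binned into *anti*, *high-anti*, *syn*.
- **Pairing schemes and breathing.** Hydrogen bonds from heavy-atom
  distance (≤ 3.5 Å) and an idealized-hydrogen angle (≥ 135°); per-frame
  classification against editable per-mismatch scheme catalogs (wobble,
  mirrored purine·purine schemes, sugar-atom acceptors, ...); breathing
  occupancy, transitions and residence times from thresholded opening
  excursions with hysteresis, split by major/minor groove direction.
- **Grooves and ions.** Minor/major groove widths from cross-strand P–P
  minima (−5.8 Å phosphate correction); radial–angular cation molarity maps
  in the local pair frame, with the exact count↔molarity conversion
  N = M · V · 6.022×10⁻⁴ ions/Å³/M.
- **Ensemble summaries.** Iterative average structure and RMSd series,
  average-linkage clustering with a medoid representative, harmonic
  stiffness constants from equipartition (k = k_BT / Var), Pearson and
  circular (Fisher–Lee) series correlations.
- **Lesion information transfer.** Per-(position, parameter) deviation of a
  mismatch ensemble from a control, with autocorrelation-corrected standard
  errors, empirical two-sided tail probabilities under the control
  distribution, Welch mean tests with effective sample sizes, and a
  transfer range from the jointly flagged cells.

Pairs are addressed in relative coordinates with the lesion at 0 (a 13-mer
spans −6…+6); the three shipped sequence contexts are d(CCATACXATACGG) and
d(CCAATTXAATTGG) (flexible) and d(CCCAGTXCTTTGG) (rigid), with X any base
against any partner.

## Worked example

```python
import numpy as np
from mmdna import (EnsembleSpec, BreathingEvent, analyze_trajectory,
                   breathing_analysis, fiber_b_table, sample_trajectory,
                   sequence_for, stiffness_constants, groove_width_profile)

seq = sequence_for("f1", "G", "T")          # G.T lesion, flexible context
spec = EnsembleSpec(
    sequence=seq, table=fiber_b_table(13), n_frames=500, seed=42,
    planted_breathing=[BreathingEvent(pair=6, start=100, stop=140,
                                      amplitude=80.0, direction="major")],
)
traj = sample_trajectory(spec)
an = analyze_trajectory(traj)

opening = an.opening_series(6)
trace = breathing_analysis(opening, reference=0.0)
print(f"lesion opening: mean {opening.mean():+.1f} deg, "
      f"breathing occupancy {trace.occupancy_pct():.1f}% "
      f"({trace.n_transitions()} events, "
      f"mean residence {trace.residence_frames().mean():.0f} frames)")

minw = np.array([groove_width_profile(traj.frame(f)).minor[6]
                 for f in range(0, 500, 5)])
stiff = stiffness_constants(an.bend, opening, minw)
print(f"helical bend   {an.bend.mean():5.1f} +- {an.bend.std(ddof=1):.1f} deg")
print(f"total twist    {an.total_twist.mean():5.1f} +- {an.total_twist.std(ddof=1):.1f} deg")
print(f"minor groove   {np.mean(minw):5.2f} +- {np.std(minw, ddof=1):.2f} A")
print(f"k_opening      {stiff.k_opening:.5f} kcal/mol/deg^2")
```

prints

```
lesion opening: mean +6.2 deg, breathing occupancy 8.0% (1 events, mean residence 40 frames)
helical bend    14.2 +- 7.5 deg
total twist    360.4 +- 15.8 deg
minor groove    5.59 +- 1.75 A
k_opening      0.00121 kcal/mol/deg^2
```

The planted 40-frame major-groove excursion is recovered as exactly one
breathing event (8% of 500 frames, 40-frame residence); the opening mean is
pulled to +6.2° by that excursion. Bend, total twist (over the 10 interior
steps: 10 × 36° at the fiber mean) and minor groove width (~5.9 Å on a
straight build) fluctuate around their B-form values under the default
noise model, and the opening stiffness is k_BT divided by the opening
variance — here dominated by the planted excursion, hence soft.

## Command line

```sh
mmdna simulate --config run.yaml         # multi-model PDB + ground truth + manifest
mmdna analyze  --config run.yaml --trajectory out/trajectory.pdb
mmdna report   out/                      # bend / breathing% / minW / twist summary
```

All thresholds (H-bond cutoffs, breathing threshold, α levels, cluster
cutoff) live in the YAML config; a fixed seed makes simulate + analyze
byte-for-byte reproducible.

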