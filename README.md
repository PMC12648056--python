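# protonpet

**In-vivo proton range verification from offline PET, via distal-R50
depth differences on the beam's-eye view.**

After proton irradiation, the tissue contains short-lived positron
emitters (¹¹C, ¹⁵O, ¹³N) whose activity distribution falls off sharply
near the end of the beam range. Scanning the patient minutes later
("offline PET") and comparing the measured activity volume against a
predicted one verifies — without any extra dose — whether the delivered
range matched the plan. This matters especially around titanium
surgical clips implanted after breast-conserving surgery: clips streak
the planning CT and could in principle perturb the proton range at the
tumor bed.

`protonpet` is a library (plus a thin CLI) for medical physicists that
implements this analysis end to end:

* **Per-line range differences.** Beam-parallel sampling lines on a
  3 mm lattice over the beam's-eye view (BEV); along each line the
  depth profile of both volumes is extracted from the skin entry and
  the distal half-maximum depth R₅₀ is located. The statistic is
  ΔR₅₀ = R₅₀(predicted) − R₅₀(measured), negative when the measured
  falloff is *deeper* than predicted.
* **Preprocessing.** Sliding-window smoothing (3×3 / 5×5, zero
  padding), target-area activity normalization, the clip/artifact
  HU-override tissue correction, rigid-translation resampling.
* **Clip-region statistics.** Per-clip mean ΔR₅₀ over the clip's BEV
  footprint at a refined 1 mm line pitch, skin-depth classification
  (2 cm boundary), control ROIs shifted 1 cm toward the boost center,
  and independent-samples t-tests between groups.
* **A synthetic forward model.** CT phantoms with clips and artifact
  shells, and predicted/measured activity pairs with *known* range
  shifts, decay-weighted isotope mixtures and Poisson noise — so the
  whole pipeline is verifiable against ground truth.

See `docs/methods.md` for the model, conventions (sign, depth origin,
half-open lattice) and limitations.

## Worked example

`examples/03_clip_analysis.py` builds a slab phantom with four Ti
clips, imposes +3 mm / −3 mm / 0 mm range shifts, adds Poisson noise at
a 500-count plateau, and runs the full analysis:

```
normalization factor: 1.0004
field dR50 = +0.11 ± 0.55 mm over 1521 lines

clip  depth(mm)  group   mean dR50(mm)  control dR50(mm)  truth(mm)
   0      15.0  lt2cm          -2.89             -1.23      -3.0
   1      12.0  lt2cm           0.19              0.15      -0.0
   2      24.0  gt2cm           0.03             -0.01      -0.0
   3      30.0  gt2cm           3.19              1.85       3.0

group comparison p-values (independent-samples t, pooled):
  clips_lt_vs_gt: 0.311
  ...
```

Each clip's mean ΔR₅₀ recovers the negated imposed shift to within a
few tenths of a mm despite the counting noise; the field-level mean is
near zero because the shifted regions cancel. The `group comparison`
block is the clip-vs-control / shallow-vs-deep table with its t-test
p-values, written to `summary.json`, `clips.csv` and `group_table.csv`
in the report directory.

The other examples show the synthetic generator and HU override
(`01_simulate_phantom.py`) and a field-level BEV ΔR₅₀ map with a
piecewise shift pattern (`02_field_range_map.py`).

## Command line

```
protonpet simulate   --config sim.yaml --out DIR    # phantom + activity pair
protonpet preprocess --config run.yaml --window 3 --target ptv --out DIR
protonpet analyze    --config run.yaml --out DIR    # full dR50 run + report
protonpet report     --clips DIR/clips.csv --out DIR
```

Volumes are NIfTI (`.nii`/`.nii.gz`) or NRRD; masks are uint8 volumes;
configs are YAML or JSON (see `protonpet.RunConfig` for keys and
defaults).

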