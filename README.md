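# tagtrax

Post-processing of animal pose-tracking trajectories and tag-effect
analysis for open-field trials.

Attaching an RFID transponder or a printed recognition marker to an insect
is the standard way to identify individuals in automated tracking studies,
but the tag itself may change the behavior being measured.  `tagtrax`
implements the full measurement chain needed to quantify such effects from
pose-tracker output (DeepLabCut-style tables): per-landmark confidence
filtering, centroid construction, pixel-to-millimetre calibration,
zero-phase low-pass smoothing, biological speed gating, three behavioral
traits, and a transformation-aware two-group linear-model comparison.  A
synthetic trajectory generator with known ground truth makes every stage
testable end to end.

## The measurement chain

For each trial (one animal in a 185 × 80 mm arena filmed at 30 fps):

1. **Confidence cutoff** — landmark observations with tracker likelihood
   < 0.6 are masked (a likelihood exactly 0.6 is kept).
2. **Centroid** — the arithmetic mean of the four body landmarks (two
   prothorax points, two cerci; antenna tips are ignored).  Frames missing
   any body landmark are treated as gaps.
3. **Calibration** — pixels → mm via per-axis scale factors; out-of-arena
   points are clamped to the boundary.
4. **Gap interpolation** — invalid runs ≤ 0.5 s are bridged linearly;
   longer gaps split the track into independent filter segments.
5. **Smoothing** — second-order low-pass Butterworth at 6 Hz, applied
   forward and backward (zero phase; effective gain is the squared
   single-pass response, 0.5 at the corner).
6. **Speed gate** — frames reached faster than 23 cm/s (the species'
   maximum recorded moving speed) are removed.

Three traits per trial:

- **average speed** \(\bar v = \frac{1}{N}\sum_i \lVert x_{i+1}-x_i\rVert \cdot f\) (mm/s),
- **number of walks** — maximal runs of inter-frame speed > 1 cm/s
  lasting ≥ 1 s,
- **exploration** — distinct cells visited of an 18-cell (3 × 6) partition
  of the arena floor.

Groups are compared per trait with OLS of the (possibly transformed) trait
on tag (untagged = reference) + experimental block, a Type II *F*-test for
the tag factor, and a Shapiro–Wilk-driven transformation ladder
(identity → √x → log x → x³); the per-study transformation choices of the
original protocol are available as presets.

## Worked example

Simulate a small study with a strong tag effect, run the pipeline, and
compare groups:

```bash
tagtrax simulate --n-tagged 15 --n-untagged 15 --blocks 4 --effect 5.0 \
                 --seed 42 --out scratch/demo
tagtrax run --manifest scratch/demo/manifest.csv --out scratch/demo_out
```

The comparison table (`scratch/demo_out/comparison.csv`, also printed by
`tagtrax compare`) reports, for each trait, the transformation chosen, the
tag effect on the analysis scale (tagged − untagged), its standard error,
*F* and *P*.  A run of the marker-scale study above prints:

```
           trait transformation  effect_estimate  std_error  f_value  p_value
  avg_speed_mm_s       identity             3.52      0.537       43 7.21e-07
         n_walks       identity             5.81      0.997     33.9 4.49e-06
n_zones_explored       identity             6.01        1.5       16  0.00049
```

i.e. tagged animals moved ~3.5 mm/s faster on average, walked ~6 more
times per 20-min trial, and explored ~6 more zones — all three effects
positive and significant, the qualitative pattern expected for
marker-style tags.  Re-running with
`--effect 1.25 --n-tagged 10 --n-untagged 10 --blocks 2` (the RFID-scale
design) leaves all three *P* values above 0.05.

The numbered scripts under `analysis/` run this same sequence as a
narrative: `01_simulate_studies.py` (both study designs as raw pose
tables), `02_process_tracks.py` (measurement chain), `03_compare_groups.py`
(statistics + figures) and `04_validate_recovery.py` (ground-truth
recovery), writing their tables under `results/`.

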