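# meshacc

Whole-surface accuracy evaluation for optical facial scanners.

Clinical 3D facial scanners (stereophotogrammetry, structured light) quote
a *nominal accuracy* measured on factory calibration objects, but their
*practical accuracy* on real faces — especially faces with jaw or
maxillofacial deformities, whose undercuts defeat optical line-of-sight —
is worse and is what actually matters in the clinic. `meshacc` implements a
whole-surface evaluation of that practical accuracy: instead of a handful
of caliper distances, it compares the *entire* test scan against a
high-accuracy reference surface of the same face.

The pipeline:

1. **Register** the test scan onto the reference: nine corresponding
   anatomical landmarks give a closed-form rigid pre-alignment, refined by
   iterative closest point (ICP) against the reference *surface* (rigid
   only — no scaling).
2. **Trim** all scans to a shared boundary (clip planes + mutual-overlap
   mask) to discard hair, ears and nostril artifacts.
3. **Partition** the face into upper / middle / lower thirds by planes
   through glabella and subnasale, normal to the vertical axis of the
   natural head position frame, with exact triangle splitting.
4. **Measure** the *3D error*: for every reference vertex `P_i`, the exact
   nearest point `P_i'` on the test surface, `X_i = ||P_i − P_i'||`, pairs
   beyond ±5 mm excluded, and

   RMS = √( Σᵢ Xᵢ² / N )

   reported globally and per facial third, plus a deviation color map
   (green ≈ 0, yellow→red positive, blue negative, black excluded).
5. **Compare statistically**: K-S normality per group, mean (SD) tables,
   per-scanner one-way ANOVA across the thirds with Levene gating
   Tukey HSD vs Dunnett T3 post hocs, and paired t-tests between scanners
   (α = 0.05).

Because clinical scans cannot ship with a library, the package includes a
first-class synthetic module: analytic face phantoms with exact landmarks,
simulated scanners (normal-direction noise, smoothing, decimation, undercut
dropout, unknown rigid displacement — all with recorded ground truth), and
multi-case virtual study generators. Every stage of the pipeline is tested
against those known ground truths.

## Worked example

```python
from meshacc import (PhantomSpec, ScannerModel, generate_phantom,
                     simulate_scan, analyze_pair)

truth, landmarks = generate_phantom(PhantomSpec(resolution=(64, 64)))
scanner = ScannerModel(name="structured_light", noise_sigma_mm=0.3,
                       smoothing_iterations=1, decimate_target=3000,
                       landmark_sigma_mm=0.5, seed=7)
scan = simulate_scan(truth, landmarks, scanner)

result = analyze_pair(truth, landmarks, scan.mesh, scan.landmarks)
print(f"ICP final objective {result.icp.final_objective:.3f} mm")
for region, rms in result.by_region().items():
    print(f"  {region:<7s} RMS 3D error: {rms:.2f} mm")
```

prints

```
ICP final objective 0.180 mm
  global  RMS 3D error: 0.51 mm
  upper   RMS 3D error: 0.46 mm
  middle  RMS 3D error: 0.44 mm
  lower   RMS 3D error: 0.55 mm
```

The simulated scanner injected 0.3 mm of depth noise, smoothed once and
decimated to 3000 triangles before hiding the scan behind a random rigid
displacement; registration recovered the pose and the measured 3D error
(~0.5 mm globally) is the noise floor plus the smoothing/decimation bias —
the same decomposition a real scanner evaluation reports. The middle face
fares best and the (feature-rich) lower face worst, the pattern such
evaluations show on deformity patients.

## Command line

Each pipeline stage is also a subcommand:

```sh
meshacc phantom   --out phantom_dir --resolution 64
meshacc study     --out study_dir --n-cases 10 --seed 1
meshacc register  --fixed ref.ply --floating test.ply \
                  --fixed-lms ref.lmk --floating-lms test.lmk \
                  --out transform.json --aligned aligned.ply
meshacc partition --mesh aligned.ply --lms ref.lmk --out-prefix case1_
meshacc compare   --reference ref.ply --test aligned.ply --max-dev 5 \
                  --out deviation.json --colormesh deviation.ply
meshacc stats     --table study.csv --out report.json
meshacc run       --study-dir study_dir --out analysis.json
```

Meshes are read and written as OBJ, STL (ASCII and binary) and PLY (ASCII
and binary, with per-vertex colors for deviation maps); landmark files are
plain `name x y z` text in millimetres.

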