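# maglevlab

Magneto-Archimedes levitation (MagLev) density fingerprinting, end to end:

1. **Physics** (`maglevlab.physics`) — force balance of a diamagnetic object
   in a paramagnetic solution between two opposed magnets, the closed-form
   levitation height, linear and analytic cuboid-magnet axial field models,
   and a Curie-law estimate of the Dy(III) medium susceptibility.
2. **Simulation** (`maglevlab.simulate`) — overdamped (Stokes) trajectories
   of a particle population with absorbing boundaries, and a synthetic
   camera model producing time-lapse grayscale frames (1 frame / 20 s,
   20 min ⇒ 61 frames).
3. **Pattern pipeline** (`maglevlab.pipeline`) — frames → ROI vertical
   intensity profiles → background subtraction → exposure normalization →
   the two-feature fingerprint: *starting position* (intensity-weighted
   centroid of the first processed frame, mm) and *levitating fraction
   area* (integral of the normalized final-time profile above a sediment
   cut).
4. **Statistics** (`maglevlab.stats`) — Fisher LDA with equal priors and
   pooled covariance, specificity/sensitivity/accuracy, pooled-variance
   Student's t tests with a pairwise p-value matrix, covariance confidence
   ellipses with numeric overlap, blind validation with donor-disjointness
   checks, and the log–log power-law exponent fit for small-angle
   scattering curves.
5. **Synthetic cohorts** (`maglevlab.cohorts`) — donor cohorts at two
   fidelity levels (fingerprint-space draws with donor/replicate variance
   components, or full simulated+rendered image series) plus a power-law
   scattering-curve generator.
6. **Workflow** (`maglevlab.workflow`, `maglevlab.cli`) — deterministic
   generate → extract → classify → report orchestration.

## CLI

```sh
maglevlab demo --seed 1 --out demo_run       # full synthetic workflow
maglevlab generate --seed 1 --out cohort.csv # fingerprint cohort CSV
maglevlab simulate --seed 1 --out frames/    # one run -> TIFFs + sidecar
maglevlab extract frames/                    # frames -> fingerprint JSON
maglevlab classify cohort.csv --positive-class PDAC
maglevlab report demo_run                    # regenerate figures/report
maglevlab physics height --sample-density 1070
```

`demo` writes `report.json` (model coefficients, confusion counts,
metrics, p-value matrix, ellipse parameters, blind-validation results —
byte-reproducible for a fixed config+seed), the fingerprint CSVs, and
scatter/boxplot/heatmap figures.

## Conventions

- SI units internally; heights reported in mm from the ROI bottom,
  rows ordered bottom-up regardless of image convention.
- z = 0 at the lower magnet face, +z up; equilibria outside [0, d] are
  reported categorically (`precipitates` / `floats`), never clamped.
- All randomness flows through `numpy.random.default_rng(seed)`;
  fixed seeds give bit-identical outputs.
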