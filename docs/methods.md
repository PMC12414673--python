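# Methods

## Scope and data model

All analyses operate on `AtomFrame` / `Trajectory` objects: coordinates
in an orthorhombic periodic box (Å, ns, bar throughout) annotated with
explicit atom roles — chain carbon (with chain and carbon index),
glycerol central carbon, phosphorus, headgroup nitrogen, water oxygen,
protein heavy atom with a β-sheet flag. Roles travel in a CSV sidecar
rather than being inferred from force-field atom names, so the pipeline
is independent of naming dialects. Coordinate files (PDB multi-model,
GRO, multi-frame XYZ) are read and written through MDAnalysis; a JSON
sidecar carries what a format cannot (box for XYZ, frame times).

## Synthetic bilayers

The generator produces *geometric fixtures with known ground truth*,
not physical trajectories: there is no force field, no dynamics, no
thermostat. What it emulates, and why that is enough for testing the
analyses:

- **Chains.** Each acyl chain is grown by internal-coordinate (NeRF)
  extension with standard aliphatic geometry: C–C 1.53 Å, C–C–C 111°.
  Each of the n−3 dihedrals is independently trans (180°) or gauche
  (±60°, random sign, the centers of the classification windows) with
  probability `gauche_prob`. The realized dihedral angles measured from
  the coordinates reproduce the requested ones to machine precision
  (tested), so the generator's gauche probability is exact ground truth
  for the gauche-fraction estimator.
- **Packing.** Lipids sit on the most nearly square nx × ny lattice
  with cell area = `area_per_lipid`, so the box xy-area is exactly
  n_lipids × APL. Two chains per lipid, 4.8 Å apart, with per-lipid
  Gaussian jitter (defaults 0.5 Å in-plane, 0.3 Å normal). Leaflets are
  mirrored about the midplane with terminal methyls at it; each chain's
  end-to-end vector lies along the normal. Chains are untilted by
  default (a tilt angle is exposed); the canonical orientation leaves a
  ~3° residual between the zigzag axis and the normal because the
  end-to-end vector of an odd-bond-count chain is not the zigzag axis.
- **Headgroups.** Three pseudo-atoms per lipid: glycerol carbon 1 Å
  outward of the chain-top midpoint, phosphorus `head_offset` = 4.6 Å
  outward of the first chain carbon, nitrogen 3.5 Å beyond. The 4.6 Å
  default makes the untilted all-trans bilayer's phosphate-plane
  separation 2 × (13 × 1.53 sin 55.5° + 4.6) ≈ 42.0 Å, the gel-phase
  thickness scale; the fluid preset (gauche 0.28, APL 60 Å²) lands near
  33 Å, and the interdigitated mode shifts one leaflet inward by 12 Å
  (configurable), giving the ~30 Å locally-thin gel signature.
- **Water.** Each leaflet gets a 22.5 Å slab of uniformly random water
  oxygens at liquid-water density (0.0334 Å⁻³), starting at the
  glycerol plane — water penetrates to the glycerol level in real
  bilayers, which gives a nonzero, realistic hydration number (~6 at a
  4.5 Å cutoff). The slab is structureless: no layering, no
  orientations, no first-shell peak in g(r).
- **Protein.** An elliptical β-barrel (defaults a = 17, b = 12 Å,
  πab ≈ 641 Å², inside the 600–700 Å² band typical of a small
  outer-membrane barrel) carves out every lipid whose glycerol falls
  inside the ellipse and inserts perimeter rings of pseudo-atoms
  spanning the bilayer; the transmembrane-most 75% are β-flagged.

Consequently the fixtures exercise the *estimators* sharply — counts,
distances, interpolation, fits all have closed-form or brute-force
oracles — but passing tests say nothing about force-field realism:
there is no pressure/temperature physics, no cooperative transition, no
chain tilt in the gel (Lβ′ tilt is not parameterized, only exposed),
no protein-induced disorder of the first shells unless constructed
explicitly. Fixtures are seeded (`numpy.random.default_rng`) and
bit-reproducible; different seeds change coordinates, never counts.

Synthetic NMR ramps follow a descending four-parameter logistic between
plateaus (defaults: midpoint 600 bar, width 100 bar, plateaus 1.0/0.2,
Gaussian noise 0.02, 11 pressures from 1 to 2500 bar); the two-state
mode splits a constant total intensity into If/Ig with the gel fraction
following the ascending logistic at the same midpoint. A shift-curve
generator emits linear or logistic-plus-linear-baseline data for the
model-comparison tests.

## Estimators and numerical choices

- **Dihedral classification.** Angles canonicalized to [0, 360);
  windows half-open: gauche+ [0, 120), trans [120, 240), gauche−
  [240, 360). The boundary convention is measure-zero for real data.
  Dihedrals are restricted to chain-carbon quadruples (11 for a
  14-carbon chain), excluding ester/glycerol torsions. Chains are
  unwrapped across periodic boundaries by minimum-image continuity
  before any torsion or S_CH evaluation.
- **S_CH.** Fixtures are carbon-only, so hydrogens are rebuilt at ideal
  tetrahedral positions (H–C–H 109.47°) from the two carbon neighbors;
  only interior carbons carry hydrogens. S is bounded in [−0.5, 1] and
  equals −0.5 exactly for chains whose zigzag axis lies along the
  normal.
- **Running averages.** Boxcar convolution; edges use shrinking windows
  (normalization by the local kernel mass), so constants are preserved.
- **g(r) / N(r).** Reference density ρ is the mean target count over
  the full box volume (the common trajectory-tool convention; slab
  normalization is not implemented). N(r) is the exact discrete
  cumulative ρ Σ g_i V_shell,i — i.e. the 4π factor *is* included so
  N(r) is a physical coordination number, and N(r_max) reproduces the
  brute-force mean neighbor count identically. Default hydration cutoff
  4.5 Å (first-minimum scale for carbon–water), exposed as a flag.
- **Shells.** Protein reference = β-flagged heavy atoms; lipid marker =
  glycerol carbon; distances are 3D with minimum image in x, y only
  (the protein is unique along z in an infinite-bilayer geometry).
  Boundaries fixed at 5 and 9.5 Å across all conditions, half-open with
  the upper edge excluded. Shell membership is instantaneous per frame;
  no residence-time smoothing. Default windows: 500 ns for shell
  distance distributions, 300 ns for everything else (the equilibrated
  tail of a production run); both are per-analysis parameters.
- **Thickness.** Per-leaflet phosphate z interpolated by
  Delaunay-triangulated linear interpolation with 3 × 3 periodic ghost
  images; nodes outside the triangulation (rare after ghosting) take
  the nearest value. Leaflet assignment by phosphorus z against the
  mean-phosphorus midplane. Collinear in-plane phosphate sets are
  rejected rather than letting periodic images fabricate a surface.
  Protein patches are ellipses centered on the upper-half / lower-half
  protein centers of mass; shell annuli grow the semi-axes by the shell
  boundaries and are made disjoint by construction. Mode detection:
  0.5 Å histogram bins, 5-bin boxcar smoothing, peaks with prominence
  ≥ 5% of the tallest; reported modes are bin centers (so a 42.0 Å
  plane reports 41.75–42.25 depending on bin phase).
- **Phase labels.** Thresholds 0.20/0.24 on f_g bracket the gel
  (~10–14%) and fluid (~28–36%) regimes; both are configurable since
  the regimes are far apart. APL enters only as a consistency check
  (gel requires APL < 55 Å²). Metastability: value inside the band,
  replicas straddling it, or split-half drift of the windowed series
  exceeding 3× the pooled standard error — an explicit stand-in for a
  by-inspection judgment. Replica aggregation is mean ± SD (ddof = 1);
  a single replica reports no spread.
- **Sigmoid fits.** Four-parameter logistic (Boltzmann), free plateaus,
  width bounded positive, `scipy.optimize.curve_fit`; initial guesses
  from the endpoints and the half-crossing. Fits are *flagged* rather
  than raised when the midpoint leaves the sampled range, the width
  exceeds it, or the amplitude is insignificant (< 3 SE) — a linear or
  flat series is therefore rejected, not mis-fit. Parameter standard
  errors come from the covariance; at 11 points the 95% interval uses
  Student-t with n−4 degrees of freedom (measured coverage 92–93% at
  noise 0.05). Midpoint recovery bias is below 1% at amplitude-SNR 10.
- **Model comparison.** Linear (2 parameters) vs logistic (4)
  chemical-shift models by AICc with a tie threshold of 2; failed
  sigmoid fits propagate as "indeterminate" with diagnostics. At the
  minimum 6 points the AICc small-sample penalty strongly favors the
  line, as it should.

## Problem sizes

Tests and the acceptance script run at desk scale: 16–64 lipids per
leaflet, 1–10 frames, 100 × 100 thickness grids (10⁴ node samples per
frame), 100–200 seeded fit replicates, ~10⁴-atom ideal-gas RDF frames.
These sizes determine every asserted quantity to well inside its
tolerance (binomial/analytic error bounds are part of the tests);
microsecond-trajectory observables (cooperative transition pressures,
replica-level metastability of real systems) are outside what geometric
fixtures can show and are not asserted numerically.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- No DCD/XTC writers; PDB/GRO/XYZ cover the fixture scale.
- The gel fixture is untilted; Lβ′ tilt must be set explicitly and no
  tilt-director analysis is provided.
- Water is structureless, so g(r) shows no molecular first-shell peak;
  hydration numbers reflect density geometry only.
- No kinetics: shell residence times, exchange rates and relaxation
  modeling are out of scope, as are spectral processing and peak
  picking on the NMR side (peak tables are the input contract).
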