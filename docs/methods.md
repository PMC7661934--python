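# Methods

## Scope and model class

`dbssteer` is a desk-scale surrogate for the finite-element + multicompartment
cable-model pipelines commonly used to generate volumes of tissue activated
(VTAs) around DBS leads. It preserves the mechanism that separates the two
steering paradigms under study — simultaneous activation sums extracellular
fields before tissue responds, alternating activation does not — while
replacing the expensive components with calibrated analytic ones:

| Component            | Full pipelines                  | This package                                   |
| -------------------- | ------------------------------- | ---------------------------------------------- |
| Field solution       | FEM with lead + encapsulation   | point-source superposition, homogeneous medium |
| Neural response      | MRG cable model + NEURON        | activating-function threshold, calibrated      |
| Threshold search     | per-axon action-potential test  | one scalar threshold, linear in amplitude      |

The simplification is deliberate: every quantity this package reports is
deterministic, reproducible to the bit, and cheap enough to recompute from
scratch in seconds.

## Field model

Potentials follow the infinite-homogeneous-medium point-source formula at
σ_bulk = 0.2 S/m, with each contact discretized into an n × n grid of
equally weighted surface sources (default n = 4; per-electrode current is
conserved exactly across its points). Cathodic stimulation carries negative
current, so potentials near the lead are negative.

The encapsulation layer (500 µm, 0.1 S/m) and the insulating shaft are
**omitted from the field computation**. The encapsulation instead sets the
axon lattice's inner radial margin (shaft radius 0.65 mm + 0.5 mm ≈ 1.15 mm):
tissue inside it is never sampled, which also creates the "no VTA" floor for
weakly driven electrodes. Electrode impedances enter only the battery-current
model, which is decoupled from the field. Output provenance records this
omission.

## Axon lattice and activation

Axons are straight, perpendicular to the shaft (oriented tangentially), with
21 nodes spaced 0.5 mm (≈ the internodal length of a 5.7 µm myelinated
fibre). They sit in half-planes every 30° at radial/vertical spacing 0.5 mm,
radial extent 6 mm, vertical extent ±5 mm around the electrode-centre plane.

An axon is activated when its peak discrete second potential difference
(the activating function, AF) meets a scalar threshold. The AF is linear in
source currents, which yields three exact properties used throughout the
suite: amplitude scaling is exact, active sets grow monotonically with
amplitude, and the MICC/Interleaving distinction reduces to
max(Σ_e profiles) vs per-electrode max — note that per-node second-difference
profiles must be summed *before* taking the peak (max of a sum is not the sum
of maxes).

**Calibration.** The threshold is fixed so that a single segmented electrode
at 1.6 mA produces a 3.00 mm VTA radius along its own centre ray. The anchor
pins the surrogate to one published operating point; the rest of the
amplitude-radius relation is then a model prediction (e.g. the titrated
single-electrode amplitudes at 2.00/4.00 mm come out at ~0.4/4.25 mA against
published 0.6/3.5 mA — right scale and ordering, not exact, as expected from
a 1/r field with no cable dynamics).

## VTA representation

Activated axon-lattice points are rasterized to a 0.1 mm voxel grid: each
active point fills the voxels whose centres lie within half the lattice
spacing (0.25 mm). The resulting binary volume is the VTA; its volume is the
voxel count × resolution³. Because the lattice is sparse (0.5 mm, 30°
planes), the voxel VTA is a union of balls around lattice points rather than
a filled region — volumes are therefore meaningful for *comparisons* (they
scale monotonically with radius and with split evenness) but are smaller than
filled-region volumes at the same radius.

VTAs built from the lattice keep their active-point set alongside the voxel
mask. Cross-sections test membership against the union of balls directly
(point set + KD-tree) instead of the voxel mask: the axon lattice is exactly
mirror-symmetric about the 60° half-plane between adjacent segments, while a
square voxel grid is not, and this choice is what makes the equal-split
(−50/−50 %) steering deviation *exactly* 0° rather than approximately so.
VTAs produced purely by voxel-set algebra (e.g. intersections) fall back to
voxel lookup.

## Steering metrics

Cross-sections are polar rasters (1° × 0.05 mm) at the vertical centre of the
activated electrodes. The rotation angle is found by scanning line angles
θ ∈ {0…179°} in 1° steps and minimizing |A_left(θ) − A_right(θ)| on the
annulus-weighted raster; ties break toward the smaller angle, and the line's
two directions are disambiguated toward the occupancy centroid (a
deterministic, rotation-equivariant convention — the equal-area *line* alone
is direction-ambiguous). The VTA radius is the maximum occupied sample along
the returned direction; deviation is the circular difference from the
expected angle (secondary-electrode fraction × 120°).

## Titration

Total amplitude is bisected until the VTA radius reaches the target
(2.00–4.00 mm grid). The controlled radius is measured on a dense polar
boundary of the same field/threshold model (0.01 mm radial step, same 1°
bisector search) rather than on the voxel raster: the lattice quantizes the
voxel-route radius at ~0.25 mm, which would make the 0.025 mm (half a metric
radial step) convergence criterion unreachable, while the dense boundary is
continuous and monotone in amplitude. The voxel VTA is separately checked to
agree with an independent dense 1-D scan to within the lattice resolution.
Bisection stops when the amplitude interval is below 0.01 mA (under the
0.1 mA precision of reported amplitudes) or after 60 iterations, and returns
the smallest bracketing amplitude; for Interleaving, the amplitude ratio is
fixed and the controlled radius is that of the union VTA. Measuring the
overall maximum radius instead of the bisector-direction radius is exposed as
`control="max"`; with the default bisector control, Interleaving needs
visibly more amplitude for uneven splits because the union's bisector points
between the two lobes.

## Energy model

Current draw is computed in SI internally (amplitudes mA, impedances kΩ,
results µA) and rounded to 0.1 µA only at reporting. The overhead current is
a constant per active program (4.9 µA; N × 4.9 µA for N interleaved
programs) rather than a general function of frequency, since the pulse
frequency is fixed at 130 Hz here. V_max may exceed the 2.8 V battery
voltage (charge-pump regime); the formulas apply unchanged. Useful exact
identities: all three paradigm formulas coincide for a single electrode, and
at equal impedances V_eq ≤ V_max with equality iff the split is uniform (so
single-source coactivation never draws more than independent sources there).

## Synthetic impedance dataset

The generator emulates the *structure* of a clinical impedance collection —
12 subjects × 2 leads × 2 directional levels × 3 electrodes × 7 visits —
with impedances from a truncated normal (mean 2.99 kΩ, truncation > 0.3 kΩ)
and AR(1) visit-to-visit correlation applied through a Gaussian copula so the
marginal stays exactly truncated-normal. Unprinted parameters are defaults
chosen once: sd 0.60 kΩ (a plausible clinical spread) and correlation 0.8
(impedances drift slowly between visits).

The default missingness — 326 complete three-electrode (lead, level, visit)
groups plus exactly one two-electrode group, 980 records in all — is the
unique composition simultaneously consistent with 980 measurements, 1958
ordered within-level pairs (Σ k(k−1)) and 978 ring-mode role permutations
(3 × complete groups); nine further groups are dropped entirely. It is an
inferred structure, flagged as such and fully configurable.

What the synthetic data does **not** emulate: real impedance distributions
need not be normal (a normality test on large correlated samples is reported
ambiguously in the source literature; this generator simply *assumes*
truncated normality), electrodes within a level are generated independently,
and no systematic post-implant drift is modelled. Tests passing on this data
show the pipeline's arithmetic and enumeration are correct, not that clinical
impedances behave this way.

## Statistics

Medians and quartiles use linear interpolation between order statistics.
The Wilcoxon signed-rank test drops zero differences and uses the exact null
distribution for n ≤ 25 (normal approximation otherwise, or when ties make
the exact distribution unavailable); an all-zero difference vector is
degenerate and returns p = 1 with a warning. Normality is tested against a
normal with estimated mean/sd, i.e. with Lilliefors-corrected critical
values. No multiple-testing correction is applied; comparisons are reported
per cell. One-sided test directions follow the study design (simultaneous
activation: lower deviation, larger volume, lower amplitude and current).
Grand summaries are reported both pooled over all 45 radius ×
fractionalization cells and as medians of per-fractionalization medians,
since the two poolings differ.

## Problem sizes and determinism

Default problem sizes — 12 half-planes × ~10 radial × 21 vertical lattice
positions (≈2 500 axons × 21 nodes), 360 × ~490 dense polar samples, 0.1 mm
voxels — were chosen so a full 108-cell grid run completes in well under a
minute on one core while keeping voxel volume differences resolvable at the
0.25 mm radius-step scale. Per-electrode unit second-difference tables are
cached (the field is linear in currents), so titration and grid runs reduce
to scaling, summing and thresholding precomputed arrays. The physics pipeline
has no randomness; the only seed in the package feeds the impedance
generator.

## Known limitations

- The activating-function surrogate has no membrane dynamics: thresholds near
  the lead are optimistic relative to cable models, so weak-electrode VTA
  failures concentrate at small radii but do not extend to large radii the
  way full cable-model results report for the most uneven split.
- Homogeneous isotropic tissue only; no capacitive (frequency-dependent)
  effects; single fibre diameter; single vertical level analysed.
- Voxel volumes are ball-union volumes on a sparse lattice (comparison-grade,
  not filled-region estimates).
- The lead's metal/insulator geometry and the FEM boundary conditions of
  reference pipelines are not modelled; agreement with published absolute
  amplitude and volume tables is therefore qualitative (ordering, trends,
  failure structure), while the energy equations, steering geometry and
  permutation counts are exact.
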