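# Methods

## Annular reconstruction and per-frame metrics

Eight crystal positions, anatomically ordered around the annulus, are
interpolated by a periodic cubic spline with **chord-length
parameterisation** (rotation- and translation-invariant) and sampled at
M = 360 points per frame — dense enough that the shoelace area of an
8-knot ellipse is within 0.2% of πab and a circle radius is reproduced to
0.012 mm at r = 10 mm. The least-squares plane is the total-least-squares
(SVD) plane of the 360 samples; its normal is oriented toward the previous
frame's normal (first frame: toward +z) so the saddle does not flip sign
between frames.

Principal axes are computed from the **projected 2D samples**, not the 3D
curve, because the orthogonal-diameter construction needs axes lying in the
measurement plane. The first axis (largest variance) is designated
intercommissural, the second septolateral; signs follow a deterministic
first-nonzero-component-non-negative convention, and a near-isotropic
projection (eigenvalue gap < 1e-6 relative) keeps the previous frame's axes
with a degeneracy flag. Axis/spline crossings are located on the dense
polygon and refined by linear interpolation between the bracketing samples;
ICW and SL are the **3D** distances between the identified annular points,
since those points live on the annulus, not in the plane.

**NPA juncture.** The non-planarity angle is the angle subtended by the
anterior and posterior horns at the juncture of the SL and ICW axes. The
two 3D axis lines are skew for a saddle, so the juncture is taken as the
midpoint of their common perpendicular. This reduces exactly to the
in-plane axis intersection for a planar annulus, and for the symmetric
saddle z = −h·cos2θ it sits midway between horn and commissure heights,
reproducing the closed form NPA = acos((h²−b²)/(h²+b²)) to machine
precision. The plausible alternative — the projected curve centroid — is
biased: the arc-length-weighted centroid of a saddle ellipse sits ~0.1·h
off the symmetry plane (the curve spends more arc length near the
commissures), and NPA sensitivity there is ≈10°/mm, a ~1.7° error for a
2 mm saddle.

Self-intersecting projections are flagged (shapely ring simplicity test)
and the magnitude of the signed area is reported rather than failing the
frame.

## Crystal localization from distances

Sonomicrometry natively measures pairwise transit-time distances; 3D
positions are recovered by classical (Torgerson) multidimensional scaling,
which is exact for noise-free Euclidean distances. The embedding is unique
only up to rotation/reflection, so each frame is aligned to its predecessor
by orthogonal Procrustes; reflections are allowed in the alignment because
MDS itself cannot fix chirality. With Gaussian distance noise of SD 0.1 mm
on the 8-crystal ring the post-alignment RMSD averages ≈0.35 mm — the
nearly planar ring amplifies out-of-plane error — which is the empirical
bound frozen into the tests.

## Beat detection

ED is defined physiologically by two coinciding signatures: the onset of
the dP/dt upstroke and the lower-right corner of the PV loop. Detection
localises beats where the 5-sample-smoothed dP/dt crosses 10% of the
within-beat dP/dt maximum, rejects candidate crossings not followed within
6 samples by ≥25% of the global dP/dt maximum (noise blips near threshold
otherwise corrupt the beat-spacing statistics), and then snaps ED to the
volume maximum near the crossing. The two signatures are cross-checked:
disagreement beyond 5 samples flags the beat. ES is the volume minimum in
each ED-to-ED window and SP_max the pressure maximum. On simulated records
spanning 80–160 min⁻¹ with pressure noise up to 1 mmHg (750 records tested)
ED is recovered within one sample and ES exactly.

## Volumes and wall thickness

LV volume uses the two-axis ellipsoid V = (π/6)·D²·L (mm³ → mL) on
endocardial axes D_endo = D_epi − 2·wt and L_endo = L_epi − wt_apical.
Within a beat the equatorial wall thickness is interpolated linearly
between its ED and ES values **along the contraction state** — the
emptying fraction (V − ESV)/(EDV − ESV) — rather than along sample time.
This mirrors incompressible-myocardium behaviour (the wall thickens as the
cavity empties), keeps the epicardial diameter a monotone function of
cavity volume so that reconstructed-volume extrema fall on the true ED/ES
samples, and makes the interpolation a well-posed fixed-point problem
(4 iterations; the time-linear variant admits a self-consistent wrong ES).
The Kelley BSA formula 734·BW^0.656 is evaluated in cm² and divided by 10⁴
(58 kg → 1.053 m²); the literal m² reading would give a four-order-of-
magnitude absurdity.

## Kinematics

Δr uses the within-beat maximum as the percent denominator, giving a
bounded [0, 100]% quantity. Descending segments are runs of ≥3 consecutive
samples with negative central-difference derivative of the 5-sample
moving-average series. v̄ — the average first derivative over those
segments — is evaluated as **net drop divided by elapsed time between the
bracketing extrema**, with each extremum's time and value refined by a
3-point parabolic fit of the raw series. The naive per-sample mean of the
smoothed derivative is biased low by ~10% at 117 Hz sampling: smoothing
shifts the derivative sign changes toward the flatter side of each
extremum, inflating the run by 1–3 near-zero-derivative samples on an
~18-sample descending limb. The drop/duration form is the same mean
derivative but insensitive to how run boundaries fall on the grid: a
2 Hz sinusoid's analytic mean 2Aω/π is recovered to 2·10⁻⁴ and the
simulator's prescribed v̄ to better than 1%. Per-beat slices are
left-padded by the smoothing window so an extremum sitting exactly on the
ED boundary can be refined. v̄ is reported as a positive magnitude, in
metric units per second; a beat with no descending run yields a flagged
missing value. Time normalisation uses linear interpolation onto K = 100
points; the first beat of a record has no previous-ES reference and its
fractional-change curve is flagged missing rather than self-referenced.

## Synthetic data generator

The generator's defaults are the emulated study's baseline conditions:
HR 135 min⁻¹, 8.53 ms sampling, MAA_i-ED 607 mm² m⁻² at BSA 1.053 m²
(58 kg), ACI-ED 0.71, NPA-ED 169°, cyclical drops 21.2% (MAA), 0.12 (ACI)
and 10.3% (NPA), E_max 2.66 mmHg mL⁻¹, V₀ 15 mL, EDV 120 mL, EDP 9.8 mmHg.
The saddle semi-axes a(t), b(t) and height h(t) are solved from the
prescribed MAA/ACI/NPA waveforms, so truth MAA = π·a·b, ACI = b/a and the
NPA closed form hold exactly at every sample. Waveforms use a C² bump
(cosine of a monotone C¹ Hermite time-warp, minimum at 35% of the cycle):
a C¹ piecewise-cosine was rejected because its curvature jumps exactly at
the extrema, where no physiological signal has a kink and where any
quadratic-fit extremum refinement is biased. Crystals sit at equidistant
angular stations (optional jitter), with optional i.i.d. positional noise
and slow rigid-body motion; all default to zero, emulating the suspended-
ventilation, sub-0.03 mm-resolution acquisition.

The ventricle is a time-varying elastance P = E(t)(V − V₀) with
raised-cosine activation (peak at 35% of the cycle), a small aortic valve
resistance (0.004 mmHg·s/mL) into a two-element windkessel
(R = 0.39 mmHg·s/mL, C = 4 mL/mmHg), and resistive filling
(0.002 mmHg·s/mL) from a constant venous pressure chosen to hit the target
EDV; eight warm-up beats let the windkessel settle. The small valve
resistance pins ejection stall to just after peak elastance, so the
minimum-volume ES points fall on the line ESP = E_max(ESV − V₀) to within
~0.7% and their fitted slope recovers E_max within 1%; the recorded
peak-elastance points lie on the line exactly. Because a single linear
ESPVR through (E_es = 2.66, V₀ = 15, EDV = 120) with ESP ≈ 70 mmHg implies
SV ≈ 80 mL, the simulated ejection fraction (~65%) is higher than a real
pig's — linearity is kept because it is the property the estimator tests.
Truth EDV/EDP are recorded at the exact beat-phase-0 crossing during
integration (E = E_min there); sample-level EDP jitters ~1.8 mmHg with the
beat-to-grid phase, as it would in real recordings.

Protocols: ICC multiplies venous pressure by 0.93 per beat from beat 1
(fixed E_max → exactly linear ESPVR; 20% EDP drop by beat ~5) and shrinks
the annular area mildly with preload; AO ramps the windkessel resistance
toward 6× baseline (per-beat approach factor 0.65) until SP_max plateaus
(<2% beat-to-beat change, reached well within 20 beats), dilating the
annulus by up to 8% and flattening the saddle toward NPA 171°. Epicardial
dimension traces are emitted with the volume-linear thickness law above,
so the analysis-side inversion is exact at ED and ES.

## Regression layer

Subject-level kinematics are regressed on E_es by OLS; r² is the squared
Pearson correlation, the slope's p-value and 95% CI come from the
t-distribution with n−2 df, and the mean-response band uses the standard
hat-matrix form. Coverage of the true slope is 95% ± 0.5% over 10⁴
simulated cohorts at n = 10. The virtual cohort couples the prescribed MAA
cyclical reduction to contractility (slope 8 percentage points per
mmHg·mL⁻¹, residual SD 4 pp around subject E_es ~ N(2.66, 0.85)), sized to
give r² ≈ 0.74 in expectation. Repeated-measures ANOVA and post-hoc
multiple comparisons are deliberately out of scope; the package emits
descriptive state summaries and the regression only.

## Problem sizes

Default verification runs use 12-beat baseline records (~625 frames at
117 Hz), 50 records for the detection sweep, 200 Monte-Carlo repetitions
for the E_es noise study and 10⁴ repetitions for CI coverage; the entire
suite plus the acceptance script completes in about a minute on one core.

## What the simulator does and does not establish

Passing the recovery suite shows the analysis chain is exact on data that
satisfy its assumptions: an elliptic saddle annulus, equidistant crystals,
uniform sampling, a monotone wall-thickness/volume relation and a linear
ESPVR. Real annuli are D-shaped rather than elliptic, crystal suturing is
imperfect, respiration and pericardial motion are richer than the
generator's rigid-body option, and real ESPVRs are linear only locally;
none of these are exercised by the defaults, so agreement with the
generator bounds algorithmic error, not physiological fidelity. Leaflet,
chordal and papillary geometry, echo segmentation and frequency-domain
analysis are out of scope.
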