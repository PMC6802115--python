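# Methods

## The generative sheet model

`SheetModelParams` collects the geometric and observation constants used by
every simulator. Defaults (all lengths nm):

| parameter | default | meaning |
|---|---|---|
| `dimer_label_distance` | 11 | separation of the two fluorophore labels of one dimer |
| `intra_filament_spacing` | 5 | axial spacing of dimer centres along a filament |
| `tilt_deg` | 40 | angle of the dimer long axis against the filament axis |
| `dimer_length` | 22 | physical dimer length; `filament_width = 22·sin 40° ≈ 14.1` |
| `filament_lateral_spacing` | 14 | centre-to-centre spacing of laterally packed filaments |
| `sheet_fraction` | 0.4 | fraction of molecules assembled in the sheet patch |
| `detection_prob` | 0.1 | probability that a label yields a localization |
| `accuracy_xy` | 20 | focal-plane localization sigma |
| `z_accuracy_factor` | 2 | axial sigma = factor × focal-plane sigma |
| `alignment` | parallel | antiparallel flips alternate filament axes |

The lateral spacing equals the filament envelope width (filaments in side
contact); the packing distance is otherwise a free choice.

A simulated *observation* is: generate ground truth → Bernoulli thinning at
`detection_prob` → independent Gaussian displacement per label
(σ_x = σ_y = `accuracy_xy`, σ_z = 2×) → draw exactly `n` signals without
replacement. Thinning precedes noise because detection failure is physically
upstream of localization error. Points displaced outside the region are
kept; region selection is a separate downstream step. Free (non-sheet)
dimers are placed uniformly in the 3D box with the pair axis uniform in the
membrane (xy) plane — dimers lie on membranes in the motivating
observations; a 3D orientation would only soften the 11 nm signature
further. The sheet patch is a single square planar patch at the box mid-z:
the filament count is chosen so the patch is roughly square
(`n_per·5 ≈ n_fil·14`), filaments span the patch, and "40% of molecules"
is interpreted as 40% of labels rounded to whole dimers.

All generators are bitwise reproducible given (seed, params, box); one
`numpy.random.SeedSequence` master seed is split deterministically into
per-operation substreams.

## The neighbour statistic and its null

For a point pattern, every ordered pair (a, b) with 3D Euclidean distance
`d ∈ [5i, 5(i+1))` nm increments shell `i`; only `i = 2..9` (10–50 nm) is
reported, because shorter distances are dominated by repeated localizations
of single fluorophores and carry large fold variance. Bin edges are
half-open, so `d = 15` falls in `[15, 20)`. The implementation uses a
KD-tree with a 50 nm cutoff; its correctness is defined (and tested)
against a brute-force all-pairs enumeration, not the index.

The null is complete spatial randomness: 20 independent uniform patterns
with the *same* number of signals in the *same* box. The fold increase is
`observed count / mean null count` per bin, with the null-relative SD
(`SD(null)/mean(null)`) as the band for observed curves; model curves
(dimer field, FFO sheet) carry the SD across their own 20 simulated trials.
No explicit edge correction is applied: since the null occupies the
identical box, boundary depletion cancels to first order in the ratio.
Bins whose null mean is zero are reported as undefined (NaN), not zero.

## Classification

`classify_pattern` assigns an observed pattern to the nearest of the three
generative models by the summed squared per-bin z-score against each
model's simulated reference ensemble (the ensemble's own per-bin mean and
SD, SD floored at one count). Two deliberate design choices:

* Classification shells extend to 100 nm (`i = 2..19`) even though reported
  profiles stop at 50 nm. The dimer field and CSR differ mainly in overall
  neighbourhood density — axial localization error spreads free dimers out
  of the slab, diluting every shell in proportion to its volume — and that
  signal accumulates with radius. On the reported 8 bins alone the two
  models overlap substantially at the default observation conditions
  (only ~1% of dimers have both labels detected); with shells to 100 nm the
  misclassification rate measured over 300 Monte-Carlo patterns per model
  is ≈0–1%.
* Reference ensembles default to 50 trials (fold *curves* keep the
  conventional 20): the z-score denominators are estimated SDs, and more
  trials keep their estimation noise from dominating the decision.

## Localization preprocessing

* **Merging**: signals in the same 160 nm camera-pixel grid cell (anchored
  at the ROI minimum corner, xy only) in consecutive frames (gap of exactly
  1 continues a run; anything larger breaks it) are replaced by their
  inverse-variance weighted mean (z averaged with the same weights), with
  quadrature-combined accuracy `σ = (Σσ_k⁻²)^(−1/2)` and the run's first
  frame. Whether the original pipelines averaged or kept the brightest
  signal is not observable from the data model; the weighted mean is the
  statistically efficient choice.
* **Drift**: per z stack, a 2D histogram (20 nm bins) is registered to the
  first stack by the FFT cross-correlation peak with parabolic sub-bin
  refinement; alternatively a user-marked fiducial cluster is tracked by
  centroid. Correction subtracts each record's per-stack xy vector.
* **Slicing**: z slices are half-open slabs `[c − t/2, c + t/2)` (60 nm
  default) so that disjoint slices partition the table exactly.

## Rendering

Each signal contributes an axis-aligned anisotropic Gaussian with
σ_xy = its accuracy and σ_z = 2× that, evaluated on an isotropic voxel grid
(10 nm default), truncated at 4σ and renormalized per kernel so each signal
deposits exactly unit mass. Total mass therefore equals the signal count
and rendering is linear in the table; both are tested to 1e-6. Slab
extraction sums voxel layers whose centres fall in the half-open slab.

## Striation images and periodicity

`render_striation_image` is a noise-free stand-in for an electron
micrograph of a sheet patch: each dimer row of the lattice is drawn as a
uniform ridge perpendicular to the filament axis at its axial position
(5 nm comb), splatted with a σ = 1 px Gaussian. Ridges — not per-label
point splats — are used deliberately: micrograph contrast integrates
protein density across the dimer, whereas a coherent 2D lattice of point
labels concentrates spectral power in mixed-index reciprocal peaks (e.g. a
~7 nm lateral half-period, since labels sit near ±1/4 of the lateral
spacing) rather than at the dimer-row pitch the images actually show.

`power_spectrum` subtracts the mean, applies a Hann window (suppresses
edge ringing; moves only sidelobes, not peak positions) and returns the
centred squared-magnitude DFT with frequency axes in nm⁻¹.
`dominant_period` searches a period band (default 3–10 nm) for the
strongest off-centre peak on a σ = 3 px smoothed copy of the spectrum; the
smoothing exists so that the maximum over ~10⁴ exponentially distributed
power bins of a featureless image does not exceed a fixed
significance threshold by chance. Significance is peak power over the mean
of a same-|f| annulus with the peak and its Friedel mate excluded; below
the threshold (default 3) a "no periodicity" result is returned rather
than an error. The peak is refined by per-axis parabolic interpolation
(period accurate to ≲0.01 nm on synthetic lattices, invariant to ±0.1 nm
under 30° image rotation); a power cross-section along the peak direction
through the origin is always reported.

## Problem sizes and numerical choices

Statistical checks run at n = 3000 signals in a 2 × 2 × 0.3 µm box with
20-trial nulls (the observation scale of the motivating experiments);
calibration uses 40 replicate seeds, classifier recovery 20 patterns per
model, and the analytic CSR cross-check a 4 µm cube where boundary
depletion of the outermost shell is <2% — in the 0.3 µm slab it reaches
~8%, which is why the closed-form comparison is done in a cube while the
fold statistic never needs it (matched-box cancellation). Ties at bin
edges always resolve to the upper bin (half-open intervals). Degenerate
inputs (empty tables, singleton patterns, constant images) return empty or
zero results rather than raising, except where the request itself is
inconsistent (odd label counts, Nyquist-violating pixel sizes, sheet
patches larger than the box).

## Limitations

* No photophysics: blinking/re-activation is reduced to the frame-merge
  rule plus a single detection probability.
* Sheets are a single planar patch parallel to the focal plane; membrane
  curvature (liposome surfaces, cup rims) is not modelled, which inflates
  the realism gap for strongly curved regions.
* The striation generator models the 5 nm dimer-row repeat only — no CTF,
  stain granularity, or multi-domain mosaics; passing the periodicity
  closure therefore shows the analyzer recovers a known lattice pitch, not
  that it is robust to micrograph artefacts.
* Drift estimation assumes structure-rich fields (autocorrelation) or an
  isolated bright cluster (fiducial); featureless sparse fields can defeat
  both, and only xy drift is corrected.
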