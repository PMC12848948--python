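# Methods

condensekit quantifies condensate and nucleoprotein-filament imaging data
through five independent analysis stages, each validated against a synthetic
generator that provides exact ground truth. This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish about real data.

## Brightfield droplet-edge statistic

**Model.** In slightly defocused brightfield, an in-focus condensate appears
as a refractile object with a sharp rim, so the degree of phase separation
in a field of view can be scored without segmentation: estimate per-pixel
intensity derivatives, select pixels whose gradient magnitude is extreme,
and report the selected area fraction.

The derivative estimate is the 5-tap Farid–Simoncelli optimal filter pair —
a smoothing kernel `p = (0.0377, 0.2492, 0.4264, 0.2492, 0.0377)` applied
along one axis and the matched derivative kernel
`d = (−0.1096, −0.2767, 0, 0.2767, 0.1096)` along the other — combined as
the magnitude √(gx² + gy²) with reflect-padded borders. The selection rule
is `magnitude > k_sd · σ`, with σ the standard deviation of the
gradient-magnitude image computed per field and `k_sd = 10` by default
(exposed in every entry point for sensitivity analysis). The per-sample
statistic is the mean edge fraction over the fields of one sample
(typically five), its error the sample SD, and the reported value is the
sample mean divided by the mean of a non-phase-separating reference imaged
with the same optics. Thresholding the magnitude rather than the signed
derivatives, and computing σ per field rather than pooled, are package
choices; both alternatives change the absolute fractions but divide out in
the normalization.

**Degenerate cases.** A perfectly flat field has σ = 0 and is assigned
fraction 0. A reference whose mean fraction is 0 cannot normalize anything;
the error message points at the missing speckle background, because the
reference's role is precisely to carry the optics' fixed speckle
contribution.

**What the statistic can and cannot see.** Out-of-focus droplets are
suppressed (their gradients are smaller), which is the intended behaviour.
The statistic saturates when edge pixels stop being rare: once the
rim-pixel fraction f approaches `1/k_sd²` (1% at k_sd = 10), σ is dominated
by the rims themselves and selection collapses. The synthetic defaults
(768×768 fields, ≤ 50 droplets of radius 3–6 px) keep f well below that
regime, as do typical experimental fields.

## Fluorescence partition coefficients

`PC_i = ⟨I⟩_condensate-i / ⟨I⟩_background`, with the background defined as
every pixel outside all condensates dilated by `exclusion_ring_px = 3`
(ring exclusion keeps edge halos out of the dilute-phase estimate; setting
it to 0 reproduces the literal all-outside-pixels definition). Mean — not
median — intensities are used throughout. PC is invariant under
multiplicative intensity rescaling but **not** under additive offsets;
images are used as acquired.

Segmentation offers two modes behind one interface. `threshold` applies
Otsu's threshold to the image smoothed at the *smallest* configured scale
(default scales 1, 2, 4 px): light smoothing suppresses shot noise while
leaving condensate boundaries in place, whereas thresholding a
heavily-smoothed image displaces boundaries by roughly the smoothing width
(measured per-condensate Jaccard on the default Poisson suite: ≥ 0.96 at
σ = 1 vs ~0.70 at σ = 4). A guard rejects Otsu splits of structureless
fields (foreground–background separation below 2σ of the smoothed image),
so constant or pure-noise images yield an empty mask with a warning.
`trained` fits a random-forest pixel classifier on a standard feature stack
(per scale: smoothed intensity, gradient magnitude, Laplacian of Gaussian)
from sparse annotations, ≥ 20 pixels per class; it is a minimal supervised
stand-in for interactive pixel-classification tools, not a re-implementation
of one. Both modes share the postprocessing: connected components
(8-connectivity by default), minimum area 9 px.

Bias note: automatic segmentation includes the partial-coverage edge band
of each condensate, which dilutes the measured mean PC by a few percent at
E = 3 on the synthetic suite (2.91 measured vs 3.0 true); with ground-truth
interior masks the estimator is unbiased and recovers E within sampling
error.

## Single-molecule localization

Detection: per-frame 3×3 local maxima above `median + k_detect ·
(1.4826 · MAD)`, with `k_detect = 5`; any two candidates within one fitting
window (9×9 px) are both discarded — no multi-emitter fitting is attempted.
Fitting: pixel-integrated 2-D Gaussian (erf differences over pixel edges)
plus constant background, minimized by least squares with inverse-variance
shot-noise weights `1/√max(model, 0.25)` — effectively a Gaussian
approximation to the Poisson likelihood. On noise-free input the fit is
exact to optimizer tolerance (≤ 10⁻³ px); under shot noise at N = 1000
photons the measured RMSE is ~0.039 px against the σ/√N = 0.038 px bound
(unweighted least squares measures ~0.054 px, which is why the weights are
there). The per-event precision estimate is the simple Thompson-style
`σ_psf/√N`, ignoring background and pixelation corrections — adequate at
the moderate backgrounds of the synthetic scenes and flagged as approximate.

Rendering is a 2-D histogram at `sr_pixel_nm` with optional per-event
Gaussian blur (by fitted precision or a fixed width); blur kernels are
renormalized after truncation so total rendered mass always equals the
event count.

The blink generator models binding-site kinetics as memoryless per-frame
Bernoulli ON events; a real imager strand has correlated ON/OFF dwell
times, so the generator validates the fitter and the geometry pipeline, not
kinetic inference. Photons of each ON event are drawn Poisson and
distributed multinomially over the pixel-integrated PSF, so per-pixel
counts are Poisson while the in-field frame sum conserves the drawn photon
count exactly — convenient for conservation tests. Camera pixel size and
photon budget are free parameters (defaults 130 nm, 1000 photons) since the
imaging conditions they emulate do not pin them down.

## Filament tracing

Pipeline: render localization table at `sr_pixel_nm = 10` → Gaussian smooth
at `smooth_nm = 30` → threshold at `min_density = 0.02` smoothed counts per
SR pixel → remove components < 20 px → skeletonize → build the 8-connected
skeleton pixel graph (redundant diagonals dropped) → prune spur branches
shorter than `prune_spur_nm = 100` → decompose each component greedily,
longest endpoint-to-endpoint Dijkstra path first, leftover pure cycles
emitted as closed traces. The decomposition is deterministic given the
mask.

Two length-bias corrections are applied, both measured on generator truth:
a 7-node sliding-mean smooth of the pixel chain removes the staircase
overestimate of 8-connected paths (up to ~7% on oblique curves; circles
read +6% raw, +0.2% smoothed), and each free end (skeleton degree 1) is
extended along its local tangent to the mask boundary, compensating
skeleton end retraction (~half the mask width per end; 2.1 µm lines read
−5% uncorrected, within ±4% corrected). Closed traces need neither
correction beyond the smoothing. Residual errors on the default synthetic
suite: < 5% for single units, < 2% for k-unit tethers (the end effect
amortizes over length).

`min_density` trades continuity against resolution: at the generator's
event density (0.1 /nm) the smoothed ridge amplitude is ≈ 0.12, so 0.02
tolerates the Poisson dips that fragment long filaments at higher
thresholds, but parallel filaments merge unless separated by ≳ 5× the
smoothing width (at `min_density = 0.05` the 5× separation resolves; ~4×
does not at either setting). Clustered/bundled structures are therefore
reported as clusters — components with ≥ 2 traces or any skeleton junction
— rather than resolved into members closer than that limit.

Inter-puncta spacing reproduces, objectively, the manual measurement of
counting pixels between consecutive bright spots along a filament: puncta
localizations are clustered (DBSCAN, eps 60 nm, min 5 events), cluster
centers are projected onto the nearest trace vertex within
`assign_radius_nm = 150`, and consecutive arc-length differences are the
spacings. Centers beyond the radius are counted as unassigned. On k-unit
tether scenes (unit 2100 nm) recovered spacings are within ~1.5% of the
unit.

All geometry is carried in nm (x = column, y = row, pixel centers at
integer coordinates); population statistics are reported in µm.

## AFM stack processing

Only the two corrections the data demand before interpretation: per-frame
subtraction of the least-squares first-order plane (idempotent; optional
per-scanline median leveling behind a flag, off by default) and per-pixel
median projection across frames (midpoint convention for even counts).
Leveling precedes projection so a drifting tilt cannot bias the median.
The projection rejects any artifact confined to fewer than half the frames
— exactly, for odd frame counts without noise. Higher-order flattening is
out of scope.

## Synthetic scenes and the limits of what passing tests show

Every generator is a pure function of (spec, seed): one
`numpy.random.SeedSequence` per call, spawned into named child streams, so
regenerating any scene is exact. Ground truth (droplet geometry, label
masks with the 1-px antialias band excluded from interior masks, parametric
curves with exact arc lengths, junction coordinates, per-event ON draws,
outlier frame indices) is emitted alongside the data and is the only
oracle the tests use.

Deliberate idealizations: brightfield droplets are a dark disk with a
bright 2-px rim (the typical defocused appearance) rather than a physical
optics model; the fixed speckle background combines a smooth mottle with
sparse sharp dots, because real optics speckle contains sharp features —
without them a droplet-free reference would have edge fraction exactly 0
and reference normalization would be undefined; condensates are hard disks
with a 1-px antialiased edge; filaments are circles, lines, or
sinusoid-perturbed curves resampled to exact arc length, with bundles
rendered as curves crossing at a shared anchor; there is no stage drift, no
PSF aberration, no multi-emitter overlap handling, and no camera gain
model. Passing tests therefore demonstrate correctness of the *computations*
under known geometry and noise, and calibrated statistical behaviour under
Poisson/Gaussian noise — not robustness to the full variability of real
microscope data. Default scene sizes (768² brightfield fields, 256²
condensate fields, ≤ 50-emitter movies of ≤ 200 frames, single-field
filament scenes) were chosen as the smallest at which the statistics of
interest are comfortably resolved.

The filament presets mirror the length scales of single vs end-to-end
tethered nucleoprotein filaments (unit contour length 2100 nm, population
SD 400 nm, k-unit tethers with k − 1 junction puncta); recovery tests
assert against the generator's own parameters, not against any
experimental value.
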