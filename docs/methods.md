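# Methods

## Problem

A pedicle screw must stop before it breaches the cortical (compact-bone)
wall of the vertebra. A needle probe carrying one source and one detector
fiber (200 um cores, 200 um center-to-center) measures diffuse reflectance
ahead of its tip; because spongy (trabecular) bone scatters more strongly
than compact bone, the detected signal changes *before* the tip reaches the
wall. Two quantities make this usable for guidance:

* **detection depth** — how far ahead of the tip the probe can sense the
  boundary; this sets the maximum alarm distance; and
* an **alarm threshold** — an interval of a scalar spectral summary
  ("pattern factor") whose value indicates the tip is within one detection
  depth of the wall.

## Photon transport model (`pedprobe.mc`, `pedprobe._kernel`)

Photon-packet Monte Carlo in a layered slab, MCML-style: exponential step
lengths with total attenuation `mu_t = mu_a + mu_s`, implicit capture
(packet weight multiplied by the single-scattering albedo at each
interaction, the absorbed fraction accumulated), Henyey-Greenstein
deflection with anisotropy g and uniform azimuth, and Russian roulette
below weight 1e-4 (survival 0.1, survivor weight x10). `mu_s` is derived
from the reduced coefficient by the similarity relation
`mu_s = mu_s' / (1 - g)`.

Geometry: z increases downward from the top surface (cm internally, mm at
every API boundary). The probe tip is the plane `z = H`; the packet starts
at the source-fiber position on that plane heading in +z as an infinitely
narrow collimated beam. The probe body occupies no volume. Detection is an
exact plane-crossing test: a packet crossing `z = H` upward inside the
detector-fiber disc (offset 200 um, radius 100 um) with direction cosine
`|uz| >= acceptance_cos_min` is collected and scored. The acceptance cone
is not specified by the probe's published description; the default
`acceptance_cos_min = 0.5` (60 degree half-cone) is a deliberate, documented
choice and is configurable.

Both layers share n = 1.38 and the entry is index-matched, so no Fresnel
event exists anywhere in the supported configuration; a model with
mismatched internal indices raises `NotImplementedError` rather than
silently ignoring the interface. The outer slab surfaces are absorbing
(Dirichlet): packets reaching them are terminated and logged as escaped.

Two variance/efficiency measures beyond plain MCML:

* **Distance roulette.** Packets that wander far from the detector almost
  never contribute. When a packet first exceeds a spherical shell of
  0.3 cm around the detector center it plays roulette with survival 0.2
  (survivor weight x5); the triggering shell then grows by x1.5 so a packet
  oscillating around the shell is not repeatedly taxed. This is unbiased
  (standard roulette bookkeeping) and roughly halves the cost per packet in
  the bone geometry; the kernel's weight ledger
  (detected + escaped + absorbed + roulette net = 1 per packet, enforced to
  1e-9 in tests) covers it.
* **Per-depth substreams.** A depth scan gives depth index i the seed
  `seed + i`; seeding goes through numpy's `SeedSequence` hashing, so
  adjacent integer seeds yield independent PCG64 streams. Multi-seed
  drivers space their base seeds by >= 1009 so substreams never collide.

The kernel is a scalar per-photon loop compiled with numba, consuming a
`numpy.random.Generator` stream draw-for-draw identically to a pure-Python
tracer; the test suite includes an independently written scalar tracer and
checks per-packet ledgers on a shared stream.

The recording voxel grid sometimes quoted for such simulations (axial
0.02 cm, lateral 0.005 cm) plays no role in the detected quantity, which
uses exact crossing geometry; a voxel fluence recorder was therefore not
implemented.

## Detection-depth statistic (`pedprobe.profile`)

Profiles are normalized to their first point. The flat region (default:
depths in [1.5, 3.5] mm) gives a baseline mean and sample sd. The lower
edge is not zero for a physical reason: with an absorbing top surface the
detected signal genuinely climbs ~10% between H = 0 and H ~ 1 mm, because
return paths through the tissue behind the tip plane are truncated while
the tip is within about one sampling volume of the surface (measured at
10^6 photons/depth in the bone model). Folding that real structure into
the baseline would inflate the "noise" estimate no matter how many photons
are run; the flat interval therefore starts past the climb, and stays
~0.6 mm clear of the earliest boundary influence on the deep side. Both
edges are configurable. The onset is the shallowest depth whose
normalized value deviates from the baseline by more than k sd (default
k = 2) *persistently* — at every subsequent grid point up to the known
boundary. Detection depth = boundary depth - onset depth. Choices made
where the published rule is silent: the deviation is two-sided (reduces to
the one-sided rule on declining profiles), and the persistence guard exists
so a single noise spike cannot fire the onset. The boundary position is an
input (it is known in both simulation and polishing experiments), not
estimated.

The statistic's resolution is one schedule step (0.1 mm near the boundary),
and its value co-varies with the per-depth Monte Carlo noise: the 2 sigma
band shrinks with photon count, so the onset moves shallower (deeper
detection depth) as statistics improve. At 3x10^5 photons/depth the
per-depth relative error in the bone model is ~2%, which places the onset
at 4.3-4.5 mm against the true transition (relative decline ~2.3% at
4.3 mm, 3.7% at 4.4 mm, 6.2% at 4.5 mm, measured at 2x10^6 photons/depth)
and the detection depth at 0.5-0.7 mm. The default problem size
(3x10^5 photons/depth, 41 depths, 5 seeds) is the package's chosen balance
of stability and desk-scale runtime; the classic 10^6-photon setting gives
the same modal answer.

## Pattern factors (`pedprobe.spectra`)

Spectra span 340-1020 nm. Reflectance normalization is
`R = (signal - dark) / (reference - dark)` against a ~99.9% white standard.
The three factors: trapezoidal **area** over 340-1020 nm; **peak**
(maximum, ties to the shortest wavelength); OLS **slope** over 500-550 nm
(inclusive endpoints). Factors are computed on whatever intensity scale is
given; the published tables' magnitudes (areas ~1e5, peaks ~1e2-1e3) are
raw spectrometer counts, and the printed slopes imply a reporting scale,
taken here as x1000 of counts/nm (configurable, admittedly arbitrary).
Replicate averaging is a pointwise mean of 20 readings (0.5 s sampling over
10 s); a different replicate count warns but does not fail.

## Thresholds (`pedprobe.thresholds`)

Regions: spongy / alarm / compact, where "alarm" is the zone within one
detection depth above the boundary. Four separation ratios (two on region
means, two on region extremes) are computed per factor; negative
extremes-based ratios flag overlap and are reported, never clipped. Factor
selection collapses the informal two-stage argument (means first, extremes
second) into one composite: per ratio, rank factors by descending value
(rank 1 best; a ratio whose denominator is nonpositive is ranked worst);
the smallest rank sum wins, ties broken by name. On the bundled porcine
tables this selects the area factor, with slope winning the mean-based
ratios but collapsing on the extremes-based ones — the same qualitative
story the original comparison tells.

The alarm band is the [min, max] of the selected factor inside the alarm
region, endpoints rounded half-up to integer counts (89783 and 129872 for
the bundled tables). The classifier partitions the factor axis: above the
band -> spongy, inside (endpoints included) -> alarm, below -> compact.
Group separation uses Kruskal-Wallis per factor at alpha = 0.05 by default
(no normality assumption; one-way ANOVA available).

Known inconsistencies in the bundled published ratio cells (ratio 1 for
peak and slope, ratio 4 for slope disagree with their own formulas applied
to the published aggregates) are recorded in
`pedprobe.reference.INCONSISTENT_PUBLISHED_RATIOS` and surfaced as
warnings; the formulas are authoritative.

## Synthetic data (`pedprobe.synth`)

The real phantom/porcine spectra exist only as published figures, so the
generator treats the published per-region factor means as ground truth and
invents the spectral shape: each class template is a fixed three-curve
basis (broad visible/NIR baseline with short-wavelength roll-off, a 810 nm
band, a localized 500-550 nm tilt) whose coefficients solve a 3x3 linear
system pinning area, peak and slope to the class targets (verified to 1% at
construction; in practice exact to ~0.01%).

A scan mixes templates with a weight w(H) ramping linearly 0 -> 1 across
the detection-depth zone (smoothstep optional; a Monte Carlo-derived
partial-volume weighting would be the physical alternative and can be fed
in through the configurable schedule/weights). Labels follow the depth rule
exactly. Replicates (20/depth) carry i.i.d. multiplicative per-wavelength
Gaussian noise, sd 2% — a shot-noise-like model chosen because it
reproduces the published tables' key qualitative feature: the slope factor
is far noisier within regions than the area factor (a per-replicate gain
would give all factors identical relative noise and make the
extremes-based selection stage uninformative). mu_s' follows the same
mixing weight with the same replicate noise model.

What passing synthetic tests show — and what they do not: they validate
the analysis chain (factor extraction, region summaries, ratio/selection
logic, band derivation, detection-depth recovery) under a controlled truth;
they do not validate the spectral shape model, instrument response,
wavelength calibration, chromophore physics, or inter-animal variability of
real bone.

## Numerical / degenerate-input policy

Strictly increasing grids are required everywhere; windows are inclusive;
normalization refuses nonpositive first points and nonpositive
(reference - dark); ratio denominators of zero raise; an alarm band with
coincident endpoints raises; the onset search raises a no-onset error on a
flat profile rather than returning a sentinel. All stochastic code takes
explicit integer seeds and is reproducible bit-for-bit.

## Known limitations

* The transport model is single-wavelength (690 nm optical properties);
  wavelength-resolved Monte Carlo, Fresnel interfaces, polarization and
  time-resolved transport are out of scope.
* The detector acceptance cone and the center-to-center reading of the
  200 um separation are conventions (documented, configurable), not
  published facts.
* The detection-depth statistic quantizes to the schedule step and depends
  (weakly, via the 2 sigma band) on the photon budget.
* Synthetic spectra are shape-synthetic; only their pattern-factor
  aggregates are anchored to published values.
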