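# pedprobe

Detection depth and alarm thresholds for a small-separation near-infrared
reflectance probe guiding pedicle-screw insertion.

## The problem

During spinal fixation surgery a pedicle screw must not breach the dense
cortical wall of the vertebra. A needle probe with one illumination and one
collection fiber (200 um cores at 200 um center-to-center separation)
measures diffuse reflectance just ahead of the screw track. Spongy
(trabecular) bone scatters more strongly than compact (cortical) bone
(at 690 nm: mu_s' = 17.23 vs 12.02 cm^-1, mu_a = 0.41 vs 0.21 cm^-1), so
the reflected signal starts changing *before* the tip reaches the wall.
This package answers the two questions that turn that effect into a
usable warning device, for biomedical-optics researchers and surgical-
guidance engineers:

1. **Detection depth** — how far ahead can this probe see? A photon Monte
   Carlo of the two-layer bone slab scans the probe from 0 to 6 mm (0.2 mm
   steps, refined to 0.1 mm near the 5 mm boundary). On the profile
   normalized to its first point, the detection depth is
   `boundary depth − onset depth`, where the onset is the first depth whose
   deviation from the flat-region mean exceeds 2 standard deviations and
   keeps doing so up to the boundary. For this probe the answer is
   ~0.6 mm.
2. **Alarm threshold** — which spectral summary ("pattern factor": area
   340–1020 nm, peak, slope 500–550 nm, or mu_s') best separates spongy
   bone / alarm zone / compact bone, and at what values should the device
   alarm? Four separation ratios (means- and extremes-based) rank the
   factors; the area factor wins, and its alarm band is the [min, max] of
   the alarm-region areas — (89783, 129872) counts·nm for the bundled
   porcine vertebra reference tables.

Because the underlying animal spectra exist only as published figures, a
calibrated synthetic generator (`pedprobe.synth`) emulates the insertion
experiments — class templates hit the published per-region factor means to
well under 1%, mixed across the boundary and replicated with 2%
multiplicative noise — so the whole chain is testable end to end.

## Worked example

```python
import numpy as np
from pedprobe import mc, optics, profile, synth, thresholds

# 1. Monte Carlo detection depth of the two-layer bone model
model = optics.two_layer_vertebra_model()       # 5 mm spongy over 2 mm compact
probe = optics.ProbeGeometry()                  # 200 um fibers, 200 um apart
scan = mc.depth_scan(model, probe, optics.ScanSchedule.two_step(),
                     n_photons=300_000, seed=1000)
res = profile.detection_depth(scan, boundary_depth_mm=5.0)
print(f"onset {res.onset_depth_mm} mm -> detection depth {res.detection_depth_mm:.1f} mm")

# 2. Alarm threshold from a synthetic insertion experiment
ds = synth.generate_dataset(synth.GeneratorConfig(), seed=42)
summary = thresholds.summarize_regions(ds.factor_table)
sel = thresholds.select_alarm_factor(thresholds.compute_ratios(summary))
band = thresholds.alarm_band(summary, sel.factor)
print(f"selected factor: {sel.factor}; alarm band [{band.lower}, {band.upper}]")
print("reading 100000 ->", thresholds.classify_point(100_000, band))
```

prints (the Monte Carlo line varies by ±0.1 mm with the seed):

```
onset 4.4 mm -> detection depth 0.6 mm
selected factor: area; alarm band [91221, 185239]
reading 100000 -> alarm
```

The first line is the simulated probe seeing the compact layer ~0.6 mm
before the boundary. The second block is the threshold chain on synthetic
data: area wins the ratio ranking and the derived band is the alarm-region
area interval of *that* dataset. The synthetic alarm region includes the
ramp's shallow edge, where spectra are still spongy-like, so its band is
wider than the porcine reference band (89783, 129872) bundled in
`pedprobe.reference` (the extremes-based ratios also warn about this
overlap on stderr — that is the surfacing of negative ratios working as
intended). A reading of 100000 falls inside the band: time to alarm.

A command-line interface mirrors the library:

```bash
pedprobe simulate --photons 300000 --seed 1000 --out profile.csv
pedprobe analyze-profile --in profile.csv --boundary-mm 5.0
pedprobe generate-synthetic --seed 42 --out-dir run/
pedprobe derive-thresholds --in run/factors.csv --out-dir run/
pedprobe classify --factor-value 100000 --band-file run/thresholds.json
```

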