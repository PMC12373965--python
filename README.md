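# transocular

Computational models and image-analysis tools for **transmission
interference microscopy of the anterior human eye**.

In this imaging geometry the eye illuminates itself: a near-infrared LED
spot is projected through the pupil onto the sclera, and the diffusely
back-scattered patch acts as a secondary light source *behind* the cornea
and crystalline lens.  The patch size plays the role of the condenser
aperture in classical transmission microscopy — a tightly localized spot
means low illumination NA and high spatial coherence, which strongly
enhances the interference (dark/bright) contrast of transparent cells and
nerves, at the cost of lateral resolution.  Structures appear bright on one
side of focus and dark on the other (the Gouy phase shift flips the sign of
the interference term through focus) and vanish exactly at focus.

The package is aimed at instrument builders and image analysts working with
this modality.  It provides:

| module | contents |
|---|---|
| `transocular.optics` | closed-form chain: LED spot projection → scleral diffusion `D = 2√(σ₀² + 2zl*)` → illumination NA `n·sin(arctan(r/L))` → `NA_eff = (NA_i + NA_d)/2` → `Δx = 0.61λ/NA_eff`, `DOF = nλ/NA_eff²` |
| `transocular.safety` | pulsed-illumination ocular safety budget (retina and cornea, adult and child), with margins against the permissible limits |
| `transocular.wavesim` | 2D time-domain scalar-wave simulation of the 4F imaging principle: defocus contrast and its sign inversion, transmitted/diffracted wave separation in the back focal plane, contrast vs. source size |
| `transocular.contrast` | fast analytic Gouy-phase defocus model for extended incoherent sources |
| `transocular.pipeline` | raw-frame processing: Bayer blur, fixed-pattern subtraction, 121×121 high-pass, frame averaging, pulse-frame selection, two-phase tomographic subtraction |
| `transocular.quantify` | cell density (cells/mm²), nerve length density (mm/mm²), mean cell diameter, SNR in dB |
| `transocular.phantoms` | seeded synthetic phantoms (cell mosaics, nerve layers, defocused scatterer stacks, camera artifacts) with full ground truth |
| `transocular.io`, `transocular.cli` | TIFF/PNG stack I/O with metadata sidecars; `transocular` command-line tool |

## Worked example

The clinical configuration uses a 0.3 NA objective and a 1:1 LED projection.
What resolution and depth of field does it achieve?

```python
from transocular.optics import (
    EyeGeometry, IlluminationTrain, DetectionConfig, resolution_chain,
)

eye = EyeGeometry()                      # adult: 23 mm, n = 1.4, μs' = 30 cm⁻¹
train = IlluminationTrain()              # 1.8 mm LED, 40/40 relay, 18 mm objective
det = DetectionConfig(na_detection=0.3)  # λ = 0.85 µm

report = resolution_chain(train, eye, det)
src = report.secondary_source
print(f"incident spot      {src.incident_diameter:.1f} mm")
print(f"diffused spot      {src.diffused_diameter:.1f} mm")
print(f"NA_i / NA_eff      {src.na_illumination:.3f} / {report.na_effective:.3f}")
print(f"lateral resolution {report.lateral_resolution:.1f} um")
print(f"depth of field     {report.depth_of_field:.0f} um")
```

prints

```
incident spot      1.7 mm
diffused spot      2.4 mm
NA_i / NA_eff      0.072 / 0.186
lateral resolution 2.8 um
depth of field     34 um
```

The 1.7 mm LED image diffuses to 2.4 mm inside the scleral wall; seen from
23 mm away that patch subtends an illumination NA of 0.072, which averaged
with the 0.3 detection NA gives 2.8 µm lateral resolution over a 34 µm
depth of field — enough to resolve endothelial cells (~20 µm) while keeping
a whole cell layer in focus.  The same chain with a 10 mm objective and a
0.4 NA detection gives the high-resolution variant (3 → 3.4 mm spot, 2 µm /
19 µm).

The same report is available from the shell:

```bash
transocular optics --preset adult --na 0.3
transocular safety --mode standard           # full light-safety table
transocular contrast-sweep --diameters 0.3,2.4,3,15
transocular phantom --kind mosaic --seed 1 --out mosaic.tif
transocular process mosaic.tif proc.tif --highpass-kernel 121
transocular quantify proc.tif --metric cells --pitch 1.0
```

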