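# ecshear

Laminar wall-shear design and image-based quantification of
endothelial flow responses.

Endothelial cells sense the wall shear stress (WSS) of flowing blood
and respond by elongating and aligning along the flow axis, shifting
their nucleus–Golgi polarity axis against the flow, and upregulating
shear-responsive transcription factors (KLF2/KLF4).  Quantifying these
responses in vitro needs two things this package provides as a tested,
reusable pipeline:

1. **Flow design** for a rectangular-duct flow chamber (defaults match
   a 96-well laminar-flow plate: channels 6.0 × 0.5 × 125.77 mm):
   conversions between flow rate Q, mean velocity U, pressure drop and
   floor shear stress via the plane-Poiseuille design rule
   τ = 6μQ/(wh²), plus the full rectangular-duct Poiseuille solution
   (Fourier series cross-validated against a finite-difference solve)
   for velocity and shear profiles across the channel.

2. **Image-based quantification** of flow responses: classical
   segmentation of junction / nuclear / Golgi channels; per-cell
   orientation by ellipse fit; axial circular statistics with the
   angle-doubling transform θᵢ = 2αᵢ and the polarity index

   PI = √[(1/N Σ cos θᵢ)² + (1/N Σ sin θᵢ)²] ∈ [0, 1],

   Rayleigh uniformity tests and angular histograms; nucleus→Golgi
   front–rear polarity via optimal assignment, with the signed
   flow-polarity index FPI = mean cos θ (negative = against flow);
   per-nucleus marker intensity; and qPCR relative expression by the
   Livak 2^(−ΔΔCq) method with standard-curve efficiencies.

Because raw microscopy of this kind is rarely shareable, the package
includes a first-class synthetic-monolayer generator: anisotropic
Voronoi mosaics of elongated cells whose orientations follow an axial
von Mises law of known concentration, with nuclei, Golgi, marker
levels, realistic noise — and a per-cell ground-truth table, so every
downstream stage is validated by parameter recovery.

## Worked example

```python
from ecshear import units
from ecshear.ductflow import operating_point_summary
from ecshear.pipeline import analyze_stack, flow_condition_spec
from ecshear.synth import render_monolayer
from ecshear.orientation import axial_summary

# 1. Flow design: what does 14 mL/min do in one channel?
print(operating_point_summary(units.m3_per_s(14.0)))
# {'flow_rate_ml_min': 14.0, 'mean_velocity_m_s': 0.0778,
#  'wall_shear_plate_pa': 0.7000, 'wall_shear_plate_dyn_cm2': 7.0,
#  'wall_shear_center_pa': 0.7388, 'pressure_drop_pa': 371.68,
#  'reynolds_number': 95.73, 'laminar': True}

# 2. Render a flow-stimulated monolayer (500 cells, kappa=3) and
#    recover its alignment through the full image pipeline.
rendered = render_monolayer(flow_condition_spec(seed=1))
result = analyze_stack(rendered.stack)
print(round(axial_summary(rendered.truth.orientation_deg).polarity_index, 3),
      round(result.cell_summary["polarity_index"], 3),
      round(result.polarity_summary["fpi"], 3))
# 0.83 0.846 -0.724
```

The first two numbers are the ground-truth and pipeline-recovered
polarity indices (PI ≈ I₁(3)/I₀(3) ≈ 0.81 for κ = 3: a strongly
aligned monolayer); the third is the signed flow-polarity index —
negative, because the synthetic cells polarise against the flow.

A CLI covers the same ground:

```sh
ecshear flow-design --width-mm 6 --height-um 500 --flow-ml-min 14 --viscosity-mpas 0.75
ecshear simulate --cells 500 --kappa-axial 3 --seed 7 --out run/
ecshear analyze --images run/images/flow.tif --out run2/
ecshear qpcr --table cq.csv --reference GAPDH --control static
```

Outputs are organised as `run/{config.json, images/*.tif,
tables/*.csv, histograms/*.csv, report.json}`; every summary in the
report traces back to a per-object CSV, and a fixed seed reproduces
the run byte for byte.

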