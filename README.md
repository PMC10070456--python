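# wallwaxs

Grazing-incidence wide-angle X-ray scattering (GIWAXS) analysis of the
plant primary cell wall, built around the hydrated-vs-dried onion
epidermis experiment: cellulose Iβ microfibrils embedded in a pectin
matrix are probed through the (110/1-10) and (200) reflections near
q = 1.1 and 1.5 Å⁻¹, and a broad pectin feature near 0.85 Å⁻¹.

The package is aimed at scattering practitioners who want a fully tested,
ground-truth-driven version of this analysis chain:

- **synthetic patterns** (`wallwaxs.synthetic`) — q-space detector images
  and rocking-scan azimuthal profiles with known component parameters
  (out-of-plane-textured cellulose reflections, isotropic amorphous rings,
  linear baseline, Poisson noise, missing-wedge mask);
- **reduction** (`wallwaxs.reduction`) — sector cuts (out-of-plane
  χ = −17…17°, in-plane χ = 56…90°), linear baseline subtraction, and
  background-subtracted azimuthal profiles of the (110/1-10) annulus
  (signal q = 1.0–1.3 Å⁻¹ minus background q = 0.5–0.6 Å⁻¹);
- **peak deconvolution** (`wallwaxs.peaks`) — two amorphous Gaussians
  (cuticle fixed at 1.41 Å⁻¹), two cellulose Gaussians and a line, with
  robustness variants; lattice spacing d = 2π/q, peak-height intensity
  ratio I(110/1-10)/I(200), and the Scherrer coherence length
  L = Kλ/(β cos θ) = 2πK/β_q with quadrature instrumental correction
  (K = 0.9);
- **texture** (`wallwaxs.polefigure`) — stitching image and rocking
  profiles into a complete χ pole figure, its FWHM, and the relative
  crystallinity index ∫₀^{π/2} sin(χ) I(χ) dχ;
- **fibril models** (`wallwaxs.microfibril`, `wallwaxs.debye`) — idealized
  18-chain (234432 layer arrangement) cellulose microfibrils with interior
  and/or surface-monolayer waters, PDB I/O, and orientation-averaged
  Debye-equation scattering I(q) = Σᵢfᵢ² + 2Σ_{i<j} fᵢfⱼ sin(qr)/(qr) with
  pair-distance-histogram acceleration, solvent subtraction
  I − (1−v)·I_buffer, and (200)-maximum normalization.

## Worked example

```python
from wallwaxs.pipeline import RunConfig, run_experiment

res = run_experiment(RunConfig(base_seed=1, n_replicates=3))
print(res["summary"].to_string(index=False))
```

prints (seven metrics per state, mean ± sd over three seeded replicates):

```
   state              metric      mean       sd  n
hydrated                d110  5.566640 0.001114  3
hydrated                d200  4.029648 0.000484  3
hydrated     intensity_ratio  0.516432 0.002448  3
hydrated           fwhm110_q  0.238944 0.001814  3
hydrated       scherrer_L110 23.667013 0.180101  3
hydrated    polefig_fwhm_deg 37.875560 0.121356  3
hydrated crystallinity_index 12.005655 0.436296  3
   dried                d110  5.518328 0.003790  3
   dried                d200  4.020286 0.000938  3
   dried     intensity_ratio  0.856780 0.009023  3
   dried           fwhm110_q  0.277752 0.003400  3
   dried       scherrer_L110 20.361446 0.247560  3
   dried    polefig_fwhm_deg 39.921813 0.577817  3
   dried crystallinity_index 11.808040 0.112163  3
```

Reading the table: the cellulose (110/1-10) spacing contracts from
~5.57 Å to ~5.52 Å on drying while d(200) stays at ~4.0 Å; the
(110/1-10)/(200) peak-height ratio rises from ~0.52 to ~0.86; the peak
width broadens (coherence length drops from ~23.7 Å to ~20.4 Å); and
neither the pole-figure FWHM (~38° vs ~40°) nor the crystallinity index
changes much — the texture and oriented crystalline content survive
drying.  `res["comparison"]` carries the paired t-test per metric.

The same pipeline is scriptable from the shell:

```sh
wallwaxs simulate --state hydrated --seed 3 --out img.tif
wallwaxs reduce img.tif --sector out-of-plane --out prof.csv
wallwaxs fit prof.csv
wallwaxs debye --preset 2 --out model2.csv   # monolayer-hydrated fibril
wallwaxs run --seed 1 --out results/run1
```

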