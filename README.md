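# nanoflim

Quantitative analysis of plasma-membrane receptor nanoclusters from live-cell
fluorescence microscopy, aimed at plant membrane-receptor biology but generic
in its parts:

* **Nanocluster detection** in surface-illumination (TIRF/VAEM) images —
  rolling-ball background subtraction, 2 µm Gaussian band-pass, fixed
  threshold, 8-connected particle analysis; densities (clusters/µm²), sizes
  (µm²) and receptors-per-cluster from density ratios.
* **FLIM/FRET** — per-pixel TCSPC decay fitting (mono/bi-exponential ⊗ IRF,
  wrapped at the laser period, Poisson maximum likelihood), the published
  quality filters (≥1200 photons, χ² < 2, 1500–2500 ps), FRET efficiency
  E = 1 − τ_DA/τ_D, and the interacting-pixel statistic (IPS): the
  percentage of quality-filtered pixels with lifetime below
  τ_D·(1 − 0.13).
* **FRAP** — background subtraction, scan-bleach correction by reference
  ROI, [0, 1] normalization, exponential recovery fit; mobile fraction Mf
  and diffusion coefficient D = 0.224·w²/τ½ for a bleach spot of radius w.
* **Photobleaching step counting** — exact penalized change-point
  segmentation of single-cluster traces to bound the number of fluorophores
  per cluster.
* **Synthetic data generators** for all four modalities with recorded
  ground truth, so every estimator is validated by parameter recovery.

## Worked example

Simulate a membrane image at 0.55 nanoclusters/µm² (6 receptors each),
detect clusters, then fit a synthetic FRAP trace and count bleaching steps:

```sh
$ nanoflim simulate --kind membrane --out membrane.tif --seed 1
wrote membrane.tif (610 clusters)
$ nanoflim clusters --tiff membrane.tif
516 clusters, 0.466 /um^2, mean size 0.0967 um^2

$ nanoflim simulate --kind frap --out frap.csv --seed 1
wrote frap.csv (Mf 28 %)
$ nanoflim frap --trace frap.csv --spot-radius-um 1.0
Mf 28.4 %  tau_half 79.9 s  D 2.81e-03 um^2/s

$ nanoflim simulate --kind bleach --out trace.csv --seed 1
wrote trace.csv (6 fluorophores)
$ nanoflim steps --trace trace.csv
6 steps -> 6 fluorophores at frames [6, 16, 19, 54, 90, 269]
```

Reading the numbers: 610 clusters were placed, 516 detected (clusters
closer than the diffraction-limited spot size merge — see
`docs/methods.md`), giving 0.466/µm² against a true 0.55/µm²; the mean
detected size of ~0.1 µm² (≈5–6 pixels) corresponds to an equivalent
diameter of ~330 nm.  The FRAP fit recovers the simulated mobile fraction
of 28 % and D = 0.003 µm²/s, and the step counter finds all six simulated
fluorophores.

The same operations are available as a library:

```python
from nanoflim.simulate import FlimSimParams, simulate_decay_cube
from nanoflim.flim import fit_image, apply_filters, ips_fraction

cube, truth = simulate_decay_cube(FlimSimParams(shape=(64, 64), seed=1))
image = apply_filters(fit_image(cube))           # per-pixel MLE + filters
print(image.mean_tau_ps)                         # 2305.2 (15 % FRET pixels)
res = ips_fraction(image, tau_donor_ps=2402.0)
print(res.ips_percent)                           # 15.6 (623/3988 pixels)
```

Multi-stage runs with a JSON config, provenance-echoing report and fixed
seed go through `nanoflim run --config config.json`.

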