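# massphot

Mass-photometry landing-event analysis for nucleic acids: simulate
single-molecule surface-binding data with known ground truth, detect
landing events in ratiometric differential movies, decompose contrast
distributions into Gaussian peaks, calibrate contrast against DNA length,
and recover diffusion-corrected species concentrations.

## The problem

Mass photometry (MP) weighs single molecules in solution by measuring the
tiny change in reflectivity of a glass–water interface each time a
molecule lands on the coverslip: light scattered by the molecule
interferes with light reflected at the interface, producing a localized,
PSF-shaped contrast step in a ratiometric differential movie.  Because
the contrast of one landing event is proportional to molecular
polarizability — and hence, for DNA, to the number of base pairs — counting
and quantifying landing events yields both the *length* and the *relative
concentration* of every species in a mixture, label-free, from
sub-picomole samples.

Two statistical steps carry the analysis:

1. **Length calibration.**  The contrast histogram of a dsDNA ladder shows
   one Gaussian peak per fragment.  Fitting a sum of Gaussians
   `Σ_j A_j exp(−(c−μ_j)²/2σ_j²)` and regressing the peak means μ_j on
   nominal length gives the conversion κ (contrast per bp, ≈1.22×10⁻⁵/bp
   for dsDNA); inverting it, `L̂ = (c − b)/κ`, sizes unknown molecules to
   a few bp.

2. **Diffusion-corrected counting.**  Landing rates are diffusion limited
   and scale with length as `k_i = α·L_i^β` (β = −0.72 for DNA), so short
   fragments are depleted from solution faster and are over-represented in
   a finite acquisition window `[t₀, t_final]`.  Each species' event count
   `a_i = A_i σ_i √2π` (the Gaussian peak area) is rescaled to the count an
   infinite observation would have seen,

   `a′_i = a_i · e^{k_i t₀} / (1 − e^{−k_i (t_final − t₀)})`,

   and the corrected counts are renormalized into mole fractions.  The
   average rate k is fitted on the pooled arrival times by truncated-
   exponential maximum likelihood, and α = k / ⟨L⟩^β with ⟨L⟩ an
   abundance-weighted mean length (see `docs/methods.md` for the choice of
   mean).

No public data exist for these measurements, so the package ships a
first-class synthetic-data module that generates landing-event streams
(and optional TIFF movie stacks) with exactly this kinetic, contrast and
noise structure, with ground-truth labels carried alongside for scoring.

## Worked example

Simulate one replicate of the equimolar 6-fragment dsDNA ladder
(100–2000 bp, ≈25k landing events in the 15–135 s window), fit the peaks,
calibrate, and correct the counts:

```python
from massphot import RunConfig, run_pipeline

config = RunConfig.preset("figure2_ladder", seed=1, target_events=2000)
report = run_pipeline(config, "out/")

cal = report["stages"]["calibrate"]
print(cal["mean_slope"], cal["r_squared"])
print(report["stages"]["abundance"]["mean_mole_fractions"])
```

prints (numbers from this exact run):

```
1.2201e-05 [0.9999982206094918]
{'100bp': 0.163, '200bp': 0.164, '400bp': 0.167,
 '800bp': 0.166, '1200bp': 0.169, '2000bp': 0.170}
```

The fitted slope recovers the generator's 1.22×10⁻⁵ contrast/bp to 0.01%
with R² = 0.999998 (the 2000 bp species is excluded from the fit, as its
size approaches the diffraction limit in the real experiment).  The raw
in-window fractions are strongly biased toward short fragments
(0.255 for 100 bp down to 0.081 for 2000 bp in `out/abundance.csv`); after
the diffusion correction every species returns to the equimolar 1/6 ≈ 0.167
within sampling error.

The same pipeline runs from the shell:

```bash
massphot run --preset figure2_ladder --seed 1 --out out/
massphot figures --report out/report.json --out out/figs/
```

and each stage is available separately (`massphot simulate | detect |
peaks | calibrate | abundance`), reading and writing plain CSV/JSON so any
stage can be re-run from persisted intermediates.  Movie-based runs
(`mode: full_movie`) render events into a noisy TIFF stack and recover
them with the detection stage (batch-averaged ratiometric differences,
amplitude threshold on the robust noise scale, radial-symmetry filter,
per-event 2-D Gaussian quantification).

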