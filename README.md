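# fibrilmap

Quantitative single-molecule localization microscopy (SMLM) analysis of
fibrillar label patterns, built around the question of how fibronectin (Fn)
dimers are arranged inside native matrix fibrils.

Fibronectin is secreted as a disulfide-bridged dimer that cells assemble
into fibrils. In dSTORM images of the thinnest fibrils ("protofibrils"),
site-specific labels (N-terminal, C-terminal, or internal epitopes) appear
as punctate, periodic patterns. `fibrilmap` implements the analysis chain
that turns such localization data into a molecular model of the fibril:

- **Periodicity** of a labeled epitope along a fibril, from the spatial
  autocorrelation of an intensity line profile: a fibril is *periodic*
  when the correlogram shows ≥ 4 maxima at regular spacings, and the
  repeat length `L` is the first maximum refined by quadratic
  interpolation.
- **Relative phase** of two epitopes from the normalized two-channel
  cross-correlation (in-phase: maximum at lag 0; alternating epitopes:
  minimum at lag 0 with maxima at ±L/2).
- **Single-dimer end-to-end distance** `E`, either from a two-Gaussian
  fit of a paired-spot line profile (dSTORM path) or from stepwise
  photobleaching with difference-ROI localization (step counting, plateau
  segmentation with a 5-frame minimum, per-step 2D Gaussian fits of
  plateau difference images).
- **Bundling** of protofibrils at fibril junctions via the
  thickness-independent metric `Δ = (B − A1 − A2)/B` on background-
  subtracted localization densities (Δ = 0 ⇔ pure bundling), plus
  cross-section FWHM measurements.
- **Architecture arithmetic**: with dimers staggered at repeat `L`,
  adjacent molecules overlap over `O = E − L` (errors added in
  quadrature), the key number distinguishing competing assembly models.
- A **synthetic-data generator** implementing the staggered-overlap
  protofibril model (dimer length `E`, repeat `L`, per-epitope labeling
  efficiency, antibody linkage error, localization precision, blinking
  relocalizations, protofibril bundles, photobleaching movies) so every
  stage can be validated against ground truth.

The intended users are microscopists analysing SMLM localization tables
(CSV) and photobleaching movies (TIFF) of fibrillar protein assemblies —
the methods apply to any fibril with periodic label sites, not only Fn.

## Worked example

Simulate ten protofibrils at the measured study conditions (repeat
L = 95 nm, dimer length E = 133 nm, 70 % labeling efficiency, 6 nm
localization precision) and run the periodicity analysis:

```bash
$ fibrilmap run --seed 2 --out demo_out
10 fibrils analysed, 6 classified periodic
mean periodicity 98.0 nm (s.d. 3.7 nm)
results in demo_out
```

Six of ten synthetic fibrils pass the ≥ 4-regular-maxima rule (labeling
voids defeat the rest, as in real data), and the mean refined repeat
recovers the generator's 95 nm within a few nm. `demo_out/periodicity.csv`
holds the per-fibril classification and estimates, and
`demo_out/provenance.json` the config hash and seed of the run.

Combining the measured summary statistics — mean end-to-end distance
E = 133 ± 4 nm and mean repeat L = 95 ± 2 nm — into the molecular overlap:

```bash
$ fibrilmap overlap --e 133 --se-e 4 --l 95 --se-l 2
overlap O = 38.0 +/- 4.47 nm
```

i.e. adjacent dimers overlap antiparallel over ~38 nm at their N-termini —
far more than the ~14 nm of the first five FnI modules (5 × 2.8 nm), which
implicates type III modules in the overlap region.

The same operations are available as a library:

```python
import fibrilmap as fm

table, truth = fm.simulate_protofibril(seed=1)
profile = fm.extract_line_profile(table, polyline)   # 2.5 nm bins
result = fm.analyze_profile(profile)                 # PeriodicityResult
est = fm.compute_overlap(133.0, 4.0, 95.0, 2.0)      # O = 38 ± 4.47 nm
```

Other subcommands: `simulate`, `profile`, `periodicity`, `endtoend`,
`bleachsteps`, `junctions` (see `fibrilmap --help`).

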