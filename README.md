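# dosykit

Simulation, processing, fitting and multi-spectrum peak-list filtering
for diffusion-ordered (DOSY) NMR of biofluids.

The package implements an end-to-end desk-scale workflow for
diffusion-ordered ¹H NMR metabolic profiling:

- **`dosykit.seqmodel`** — parameterization of three pulsed-field-gradient
  experiments (traditional bipolar-pair stimulated echo, relaxation-edited
  double-spin-echo train, diffusion-edited long-delay variant), gradient
  ramps, b-values and per-increment attenuation factors including T2
  weighting.
- **`dosykit.simulate`** — synthetic biofluid phantoms with known ground
  truth (a urine-like small-molecule mixture with a TSP reference, and a
  plasma-like mixture with glucose/alanine/lactate/valine plus broad
  protein, lipid and lipoprotein envelopes) and a forward simulator that
  produces gradient-incremented pseudo-2D FID matrices.
- **`dosykit.process`** — Gaussian apodization, zero-fill, FFT, automatic
  phasing, chemical-shift calibration (glucose anomeric doublet at
  5.23 ppm or TSP at 0.00 ppm), residual-water masking and robust noise
  estimation.
- **`dosykit.fitdosy`** — peak picking, per-peak decay extraction across
  the gradient ramp, exponential (Stejskal–Tanner) fitting with
  covariance-based fitting errors, and columnar peak-list files.
- **`dosykit.peaktool`** — filtering of peak lists from many spectra by
  chemical-shift ranges, fitting-error threshold and intensity floor,
  with consolidated CSV export and per-range summary statistics.
- **`dosykit.calibrate`** — gradient calibration against a doped-water
  reference (D = 1.91 × 10⁻¹⁰ m²/s); absorbs gradient-shape and
  pulse-length convention mismatches.
- **`dosykit.cli`** — a `dosykit` command-line tool orchestrating the
  full simulate → process → fit → filter pipeline from a JSON config.

Diffusion coefficients are expressed in 10⁻¹⁰ m²/s throughout the user
API; pulse-sequence parameters are SI.

## Conventions worth knowing

- `delta_total` is the *summed* duration of a bipolar gradient pulse
  pair (a "1.5 ms" per-lobe pair has `delta_total = 3.0 ms`); pass
  `delta_is_per_lobe=True` to `sequence_params` to convert. The
  simulator and fitter share the convention, and gradient calibration
  absorbs it for instrument data.
- b-values use the bipolar-LED expression
  `b = (γ·s·g·δ)²·(Δ − δ/3 − τ/2)`; the relaxation-edited train
  multiplies the effective diffusion time by `n_pairs_effective`
  (default `n_pairs − 1`).
- The Gaussian window is `exp(−(π·gw·t)²/(4 ln 2))` with `gw` in Hz of
  added line broadening.
- Water is masked (4.55–4.90 ppm by default), not zeroed.
- Fitting error = relative standard error of D from the fit covariance.

## CLI

```bash
# simulate a plasma phantom under the relaxation-edited sequence
dosykit simulate --phantom plasma --kind relaxation_edited --seed 1 --out data/

# process + fit
dosykit process --data data/ --points 65536 --calibrate-mode glucose --out proc/
dosykit fit --data proc/ --out peaks.tsv

# filter peak lists from many spectra into one CSV
dosykit filter --lists 'peaks_*.tsv' --ranges 1.44:1.50,5.20:5.26 \
    --max-error 0.2 --out table.csv --summary summary.csv

# gradient calibration from a doped-water dataset
dosykit calibrate --data water/ --reference 1.91 --out calib.json

# full pipeline from a JSON config
dosykit run --config config.json --out run1/
```

A pipeline config mirrors the CLI flags:

```json
{
  "sequence": {"kind": "relaxation_edited"},
  "phantom": {"name": "plasma", "seed": 1, "count": 10},
  "sim": {"points": 8192},
  "processing": {"gw": 1.0, "target_points": 65536, "calibrate_mode": "glucose"},
  "fit": {"threshold_multiple": 5.0},
  "filter": {"ranges": [[5.20, 5.26]], "max_relative_error": 0.2}
}
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. Re-runs
with the same config and seed are bit-reproducible; completed stages are
skipped when their artifacts already exist.

## Data formats

- Pseudo-2D datasets: a directory holding `meta.json` (sequence +
  digitization parameters, domain flag, shape) and `data.bin`
  (little-endian float64, interleaved real/imaginary, row-major
  increments × points); round-trips bit-exactly. Simulated datasets
  also carry `ground_truth.json`.
- Peak lists: tab-separated text with a fixed header
  (`ppm  D_1e-10_m2s  rel_error  intensity  flags`) plus `#` comment
  lines for the spectrum id and parameter hash.
- Consolidated tables: RFC-4180-style CSV with header
  `spectrum_id,ppm,D_1e-10_m2s,rel_error,intensity`.
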