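# blinkhp

Temporal high-pass filtering for single-molecule localization microscopy
(SMLM) in high-background samples.

SMLM resolves structure below the diffraction limit by localizing sparse,
*blinking* emitters over thousands of camera frames.  In samples with strong
autofluorescence — filamentous fungi are a notorious example, but thick
tissue and PAINT imaging share the problem — the background in a single frame
rivals or exceeds the brightness of a single molecule, and spot detection
drowns in false positives while missing real signals.  The background,
however, barely changes from frame to frame, whereas single molecules switch
on and off.  `blinkhp` exploits that difference: each pixel's intensity trace
is Fourier-transformed along time, the lowest `omega_T` percent of the
frequency axis is zeroed (with `M = T//2 + 1` non-negative bins, the bins
below `floor(omega_T/100 * M)` are removed), and the trace is transformed
back; a single global offset then restores non-negative values.  Static and
slowly drifting background vanishes identically; the broadband signature of
blinking partially survives.

The package is a small toolkit around that operation, for microscopists and
method developers who want to quantify what temporal filtering buys on their
kind of background:

* `blinkhp.filtering` — the pixel-wise temporal high-pass and a
  sliding-window median-subtraction baseline;
* `blinkhp.simulate` — ground-truth movies: blinking emitters (exponential
  on/off sojourns of mean `tau_on`, `tau_off`; lognormal per-frame brightness
  of mean `B`, SD `B/3`; pixel-integrated Gaussian PSF, sigma = 160 nm)
  overlaid on a recorded or synthetic autofluorescence background;
* `blinkhp.localize` — a transparent threshold-plus-Gaussian-fit localizer;
* `blinkhp.evaluate` — one-to-one matching against ground truth within
  160 nm and the resulting TPR (`TP/(TP+FN)`), FDR (`FP/(FP+TP)`) and
  positional-accuracy summaries;
* `blinkhp.pipeline` — seeded end-to-end benchmark experiments over
  parameter grids, with per-threshold detector tuning;
* `blinkhp.io_formats` — multi-page TIFF stacks, CSV tables, YAML configs.

See `docs/methods.md` for the models, the calibration of the synthetic
background, and — importantly — the physics of what this filter convention
does to blink pulses at high `omega_T`.

## Worked example

Simulate a dim-emitter movie on a synthetic autofluorescence background
(mean 1000 counts, per-pixel temporal SD 125 counts against signals of 500
counts), then localize it with the same fixed detection threshold before and
after filtering:

```python
import numpy as np
from blinkhp import (
    DetectorParams, FilterConfig, SimulationParams,
    generate_synthetic_background, simulate_movie,
    highpass_filter_stack, localize_stack, match_tables,
    compute_tpr, compute_fdr, localization_errors,
)

rng = np.random.default_rng(42)
background, roi = generate_synthetic_background(
    shape=(64, 64), n_frames=1000, mean_level=1000.0, temporal_std=125.0, rng=rng,
)
params = SimulationParams(b_mean=500.0, tau_on=3.0, tau_off=180.0,
                          density=2.0, n_frames=1000)
movie, truth = simulate_movie(params, background, roi, rng)
print(f"{len(truth)} ground-truth emitter appearances in {params.n_frames} frames")

detector = DetectorParams(threshold_k=4.5)
for label, stack in [
    ("unfiltered", movie),
    ("omega_T=80", highpass_filter_stack(movie, FilterConfig(omega_t=80.0))),
]:
    locs = localize_stack(stack, detector)
    counts = match_tables(locs, truth)
    err = localization_errors(counts)
    print(f"{label:>11}: {len(locs):4d} localizations  "
          f"TPR={compute_tpr(counts):.2f}  FDR={compute_fdr(counts):.2f}  "
          f"mean error={err['mean_nm']:.0f} nm")
```

Output:

```
1777 ground-truth emitter appearances in 1000 frames
 unfiltered:   75 localizations  TPR=0.03  FDR=0.31  mean error=64 nm
 omega_T=80:  314 localizations  TPR=0.12  FDR=0.33  mean error=50 nm
```

At this fixed 4.5-sigma threshold the unfiltered analysis finds 3 % of the
signals — the background's static spot-sized texture sets the noise floor —
while after temporal filtering the same threshold finds four times as many,
at the same false-discovery rate and with slightly better positional
accuracy.  (Permissive thresholds raise the unfiltered sensitivity to ~0.4,
but at ~95 % false discoveries; the benchmark in `blinkhp.pipeline` explores
those trade-offs systematically.)

The same steps are available from the shell:

```
blinkhp simulate --config sim.yaml --out-movie movie.tif --out-truth truth.csv
blinkhp filter   --input movie.tif --output filtered.tif --omega-t 80
blinkhp localize --input filtered.tif --output locs.csv --threshold-k 4.5
blinkhp evaluate --locs locs.csv --truth truth.csv --out metrics.json
blinkhp run      --config experiment.yaml --out results/
```

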