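# axonmt

Quantitative analysis of axonal microtubule organization and its response to
redox signaling, packaged as four reusable analysis arms plus a synthetic-data
generator with known ground truth:

1. **FDAP kinetics** (`axonmt.fdap`) — fluorescence decay after
   photoactivation of tagged tubulin in a neurite segment is modelled as a
   two-pool reaction–diffusion system: free dimers diffuse (D) and exchange
   with an immobile polymer-bound pool with pseudo-first-order rates k\*₍on₎
   and k₍off₎.  Fitting a decay curve yields the rates and the **polymerized
   tubulin fraction** k\*₍on₎ / (k\*₍on₎ + k₍off₎); a one-dimensional
   diffusion model provides effective diffusion constants.
2. **Microtubule array extraction** (`axonmt.smlm`, `axonmt.filaments`,
   `axonmt.arraystats`) — single-molecule localization tables are rendered to
   26 × 26 × 25 nm voxel volumes; thin optical sections are enhanced with
   line/orientation filter transforms, segmented by Otsu's method,
   skeletonized, split at junctions, and regrouped into filaments under hard
   geometric constraints (search cone 60°/40 px, gap-vector 30°, curvature
   ≤ 1 rad/µm, minimum 15 px = 390 nm).  Per-cell statistics: mass, density,
   mean length, straightness, and a unit-area length histogram (0.5 µm bins).
3. **Vesicle transport** (`axonmt.transport`) — particle detection
   (500 nm window), autoregressive-motion linking with global minimum-cost
   assignment (1 µm gate, ≤ 2-frame gaps), a 15-frame (3 s) track filter,
   and mobility classification: a vesicle is *mobile* when its net
   displacement exceeds 0.75 µm over the 60 s observation.
4. **Phosphosite comparison** (`axonmt.phospho`) — condition-specific site
   sets keyed by (gene, residue, position), microtubule-related functional
   grouping, exact set overlap between stressors, and one-sided
   hypergeometric kinase-substrate enrichment with Benjamini–Hochberg
   adjustment.

`axonmt.synth` generates all four input classes with fixed seeds and emits
machine-readable ground truth; `axonmt.pipeline` chains
simulate → analyze → report, and the `axonmt` command exposes the same
operations from a shell.

## Worked example

```bash
python examples/fdap_kinetics.py
```

```
control:
  generating rates   k_on* = 0.081/s, k_off = 0.019/s  (bound fraction 0.81)
  fitted (3 curves)  k_on* = 0.082/s, k_off = 0.019/s  (bound fraction 0.81)
h2o2:
  generating rates   k_on* = 0.070/s, k_off = 0.030/s  (bound fraction 0.70)
  fitted (3 curves)  k_on* = 0.069/s, k_off = 0.030/s  (bound fraction 0.70)

pure diffusion control: D_eff = 3.00 um^2/s (expected 3.00: no binding, ...)
```

The two presets embody the polymer fractions of untreated (0.81) and
subtoxic-peroxide-treated (0.70) axon-like processes; the fit recovers the
generating rate constants from noisy curves, and a construct without binding
returns the pure diffusion constant.  The other examples
(`filament_extraction.py`, `vesicle_tracking.py`, `phospho_comparison.py`,
`full_pipeline.py`) exercise the remaining arms the same way, each printing
recovered quantities next to the generating truth.

Command-line equivalents:

```bash
axonmt simulate fdap --preset h2o2 --n 20 --noise-sd 0.02 --seed 42 --out curves/
axonmt fit-fdap --input curves/manifest.csv --d-fixed 3.0 --out results.csv
axonmt extract-filaments --locs locs.csv --section-z 75 --thickness 150 --out outdir/
axonmt analyze-tracks --dets dets.csv --frame-rate 5 --out outdir/
axonmt phospho compare --a h2o2.tsv --b arsenite.tsv
axonmt run --config cfg.toml
```

## Method notes

See `docs/methods.md` for the governing equations, solver design, grouping
constraints, generator models, numerical choices, and known limitations.
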