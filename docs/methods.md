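# Methods

## FDAP reaction–diffusion model

A 6 µm segment of a neurite is photoactivated at t = 0 and the window
fluorescence is monitored (default schedule: 1 frame/s, 112 frames).  Tagged
tubulin is modelled as two exchanging pools on a 1D line:

    ∂f/∂t = D ∂²f/∂x² − k*_on f + k_off b
    ∂b/∂t = k*_on f − k_off b

with free dimers diffusing at D (µm²/s), the bound (polymer) pool immobile,
and pseudo-first-order exchange rates k\*_on, k_off (1/s).  Cells are at
binding equilibrium before activation, so the activated material starts as
f = k_off/(k\*_on+k_off), b = k\*_on/(k\*_on+k_off) inside the window and
zero outside.  The readout is the window integral of f + b normalized to its
t = 0 value.  The polymerized tubulin fraction is k\*_on/(k\*_on+k_off).

**Solver.** The domain is finite (default 20 × window length) with
reflecting ends.  The production solver expands both fields in the Neumann
cosine eigenbasis and propagates each spatial mode with the exact 2×2 matrix
exponential — exact in time and spectrally accurate in space, which makes
per-curve multi-start fitting tractable (~1 ms per model evaluation at 1200
modes).  Two non-smooth contributions are handled analytically: the t = 0
window integral equals the window length exactly, and the truncated-tail
mass of the bound pool (which keeps the sharp window edges) decays as
exp(−k_off t) because tail modes have Dq² far above the rates.  A
Crank–Nicolson finite-difference solver is retained
(`fdap.crank_nicolson_reference`) as an independent numerical cross-check;
it rejects time steps above the accuracy criterion dt ≤ dx²/(2D).  The two
solvers agree to ~1e-3 in normalized intensity; mass is conserved to 1e-9
(spectral) and 1e-6 (finite-difference).

**Fitting.** D is fixed during the (k\*_on, k_off) fit — joint estimation of
all three from one curve is ill-posed; D comes from the caller, e.g. a
one-dimensional diffusion fit of a non-binding construct.  χ² uses a noise
scale estimated from the last 10 frames after removing a linear trend,
falling back to unweighted least squares when degenerate.  The optimizer
runs from a 4×4 log-spaced start grid over [1e-4, 1] 1/s in log-parameter
space with bounds [1e-5, 10] 1/s; best χ² wins, ties break toward the
slower-exchange solution, and estimates within tolerance of a bound set
`at_bound`.  When (k\*_on + k_off) exceeds the sampling rate tenfold the
result carries an `exchange-too-fast` diagnostic: only the combination
D/(1+K) is then identifiable, which is exactly the fast-exchange effective
diffusion limit D_eff = D/(1+k\*_on/k_off).

**Pure-diffusion model.** The closed form for a box initial profile on an
infinite line, F(t) = erf(s) + (exp(−s²) − 1)/(s√π) with s = L/(2√(Dt)),
serves as the effective-diffusion model function; it is verified in the
tests against a brute-force heat-kernel convolution.

**Normalization.** Curves are normalized to the first post-activation frame;
no background subtraction (assumed upstream).

## Microtubule array extraction

Localization tables (x/y/z nm, frame, photons, precisions) are rendered by
plain histogram binning into 26 × 26 × 25 nm voxels — no Gaussian splatting,
since extraction operates on Otsu-binarized filter responses.  Optical
sections are sum projections of the planes whose voxel centers fall in the
half-open slab [z − t/2, z + t/2); 150 nm thus selects exactly six 25 nm
planes when aligned, and 70 nm selects two or three depending on
registration.

The extraction chain per section:

1. **LFT/OFT** — per pixel, the maximal mean intensity along a centered scan
   segment (radius 10 px) over 40 orientations, and the orientation
   achieving it (ties toward the smaller angle).
2. **Otsu segmentation** on a 256-bin histogram, followed by a second Otsu
   pass restricted to the first mask.  The line filter produces a broad
   lateral halo around each filament whose response is well separated from
   the on-ridge response; the second pass removes it.
3. **Ridge thinning** — non-maximum suppression of the LFT across the local
   OFT direction, leaving a 1–2 px ridge, then skeletonization.
4. **Spur pruning and junction removal** — endpoint-terminated side branches
   of up to 4 px are deleted (boundary-bump artifacts); branch points are
   detected by the Rutovitz crossing number (a raw 8-neighbor count would
   misclassify staircase corners) and cleared with their 8-neighborhood,
   splitting the skeleton into junction-free ordered chains.  Chains under
   5 px are discarded as residual noise.
5. **Grouping** — candidate tip-to-tip joins must satisfy every hard
   constraint: partner within 40 px and inside the 60° search cone, gap
   vector within 30° of both tip propagation directions, tip-direction
   difference ≤ 60°, endpoint-orientation difference ≤ 60°, and implied
   curvature ≤ 1 rad/µm.  Curvature is the turn between the tip tangents
   divided by the traversed arc (gap plus the two 5 px tangent-estimation
   windows); a chord-circle estimate was rejected because at
   junction-removal-scale gaps (~3 px) it demands tangent collinearity
   within ~2°, far below the pixel-noise floor, and vetoes legitimate
   rejoins.  Surviving candidates are scored
   w_sim(1 − Δθ/θ_max) + w_cont(1 − gap/r_max) with unit weights and
   accepted greedily best-first, each tip at most once per round and no
   fragment reuse; rounds repeat to a fixed point within each of the two
   grouping iterations so that filaments chopped into many pieces
   re-assemble.  Accepted joins are recorded with their constraint values
   for auditing.
6. **Statistics** — filaments shorter than 15 px (390 nm) are excluded
   uniformly (composites and singletons alike) before statistics; mass is
   the summed contour length, density the mean count of filaments crossing
   20 evenly spaced transverse lines per µm of process, and the length
   histogram uses 0.5 µm bins normalized to unit area.  Whether ungrouped
   singleton fragments below the minimum length should stay in the
   statistics is genuinely ambiguous; the cut is applied uniformly, which
   also gives the clutter-robustness check its meaning.

## Vesicle tracking

Detection smooths each frame with a Gaussian of σ = diameter/4 (500 nm
default diameter at 172 nm pixels), finds local maxima above a configurable
fraction (default 0.2) of the smoothed per-frame maximum — the acquisition
software's absolute threshold is not published — and refines positions to
the intensity-weighted centroid inside the detection window; two spots
closer than the window merge by construction.

Linking maintains, per track, a recursive per-frame velocity estimate
v ← a·v + (1 − a)·step (autoregressive coefficient a = 0.8, steps
normalized by the frame difference so gaps do not inflate them).  The
prediction x + Δf·v is compared with next-frame detections; the
prediction-to-detection matrix is solved by global minimum-cost assignment,
links beyond 1 µm are rejected, and track ends survive at most 2 missed
frames.  The recursive estimate (rather than the raw last step) is what
separates slow directed motion from 50 nm stationary jitter at the
assignment stage; with one-step estimates identity swaps at close
encounters inflate the mobile fraction by ~10 points.

Track metrics use the time between first and last detection (gaps
included).  Mobility is strict: net displacement > 0.75 µm.  Direction is
the sign of the net displacement projected on the axis from a user-supplied
reference point (cell-body/neurite transition) toward the distal process;
|projection| < 0.1 µm is "undirected".  Cell summaries report the mobile
fraction, mean velocity and speed over mobile tracks only, and per-direction
counts; zero retained tracks yield an explicitly undefined (None) fraction.

## Phosphosite comparison and enrichment

Sites are keyed by (gene symbol, S/T/Y residue, 1-based position).
Significance defaults (p ≤ 0.05 inclusive, any fold-change magnitude) are
configurable since published volcano-plot cutoffs are not printed.
Functional groups cover tubulin isoforms, nucleators, MT-binding,
tubulin-sequestering, end-binding, and MT-severing proteins; unknown genes
fall back to "unclassified".  Enrichment is the one-sided upper-tail
hypergeometric probability of the observed query/term overlap in a
user-supplied background with Benjamini–Hochberg adjustment across terms;
the kinase-substrate resource itself is supplied by the user as a
term → gene TSV.  A 31-residue window extractor (±15 around a site) exports
sequences for external phosphatase-prediction tools.

## Synthetic-data generators

Every generator is a pure function of (parameters, seed) and emits ground
truth alongside the data.

- **FDAP presets** — control (k\*_on = 0.081, k_off = 0.019) and h2o2
  (0.070, 0.030) at D = 3 µm²/s realize polymer fractions 0.81 and 0.70;
  absolute rates are chosen in the slow-exchange regime resolvable at
  1 frame/s.  Noise is i.i.d. Gaussian (default sd 0.02) with first-frame
  renormalization.
- **Arrays** — discretized worm-like chains (26 nm step, persistence length
  2 mm, matching microtubule stiffness) run nearly parallel to the process
  axis and are layered ~70 nm apart axially.  Lengths are lognormal:
  the PC12-like scenario is dominated by short microtubules
  (median ≈ 2.2 µm), the DRG-like scenario longer (median ≈ 5 µm).
  Localizations are sampled at 0.15/nm with Gaussian offsets σ_xy = 8 nm and
  σ_z = 12.5 nm (so the rendered axial feature width matches a 25 nm axial
  resolution) plus uniform clutter.  `ArrayModel.recovery_benchmark()` is a
  sparse single-layer variant with ≥ 600 nm lateral separation: filaments
  laterally closer than the line-filter support merge at extraction, and
  tips of distinct collinear filaments within the grouping search reach are
  indistinguishable from a true continuation — both resolution limits of
  the method, so per-filament recovery is only well-posed beyond them.
  The dense default scenarios remain in use for the constraint-audit and
  clutter-degradation tests.
- **Vesicles** — 60 % mobile by default; mobile vesicles run at
  0.5–1.5 µm/s with a 0.1 per-frame pause probability and 20 nm jitter,
  70 % anterograde; stationary vesicles jitter with σ = 50 nm; detections
  drop out at 5 %; 5 frames/s for 60 s.
- **Phosphosite tables** — two condition tables with an exactly controlled
  number of shared keys over a mixed pool of microtubule-related and
  generic genes; fixed fixtures reproduce the published MAP1B pattern
  (22 vs 27 sites, single shared S1772) and the 4-of-82 overlap pattern.

### What the generators do not emulate

FDAP curves have no photobleaching, background drift, or activation-profile
blur; localization tables have no blinking kinetics, drift residuals, or
camera-frame structure; vesicles do not reverse direction or interact;
phosphosite tables carry no missing-value or intensity structure.  Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the stated statistical structure, not robustness to every artifact of
real microscopy or MS data.

## Problem sizes and determinism

The default test and acceptance runs use 20 curves per FDAP condition
(112 frames each), four array sections of six filaments (~2000
localizations each), three vesicle series of 40 particles × 300 frames, and
site tables of ≤ 82 sites — sizes chosen so the full battery completes in a
few minutes on one CPU while keeping estimator noise well inside the test
tolerances.  All randomness flows through explicit seeds; reports include a
config hash and are byte-identical for identical config + seed.

## Known limitations

- Joint (D, k\*_on, k_off) estimation from a single FDAP curve is not
  attempted; misspecified D biases the recovered rates (but less so their
  ratio, hence the bound fraction).
- Extraction is per-section 2D; filaments are not traced across slabs, and
  arrays denser than the line-filter support report merged filaments.
- The tracker has no explicit merge/split handling; crossing vesicles can
  still swap identities in unfavorable geometries.
- Enrichment treats genes as exchangeable (no per-gene site-count
  weighting), matching standard kinase-enrichment counting.
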