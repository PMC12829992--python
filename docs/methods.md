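# Methods

## Model

`dopasim` integrates extracellular dopamine on a cubic voxel lattice with
periodic boundaries. Each step applies, in order, release → uptake →
diffusion (operator splitting; the ordering matters at O(dt) and is fixed
and documented here), then optionally advances receptor occupancy against
the updated field.

**Release.** Sites are placed uniformly at random, at most one per voxel
(collision-free sampling without replacement); the site count is binomial
with mean `density × volume`. Each site belongs to one of `n_neurons`
neurons; neurons fire independent homogeneous Poisson trains at the tonic
rate. Each action potential triggers, per active site of that neuron, an
independent Bernoulli release (probability R) that deposits one vesicle's
content into the site's voxel as a point source:
`Q_conc = Q/(N_A · v_voxel · EVF)`. Releases, firing, site placement and
burst draws use four independent RNG streams spawned from one seed, so
sweeps can vary one source of randomness at a time. Vesicle depletion,
paired-pulse plasticity and autoreceptor feedback are intentionally not
modelled; their net effect is folded into the in-vivo-calibrated release
probability.

**Uptake.** Michaelis–Menten, `Vmax·C/(Km+C)·dt`, floored at zero (with an
explicit step a large `dt·Vmax/Km` could overshoot; flooring is the
physical contract). `Vmax` may be a scalar or a per-voxel map.

**Diffusion.** Explicit Euler with the standard second-order 7-point
stencil and the tortuosity-corrected coefficient `Da = D/λ²`. Stability
requires `dt ≤ dx²/(6 Da)`; the operators raise an error beyond the bound.
The default tissue step `dt = 1e-4 s` sits ≈5× below the bound at the
default 1 µm voxel (voxel sizes 0.1–2 µm are supported, with `dt` reduced
automatically in the granularity check).

**Receptors.** Per-voxel occupancy follows
`d occ/dt = C·kon·(1−occ) − koff·occ`, `kon = koff/EC50`, integrated at the
simulation `dt` (the stiffest term, `kon·C` at micromolar burst peaks, is
~20–30 s⁻¹, safely below 1/dt). Bound dopamine does not buffer the field.
Affinity sweeps hold the measured `koff` and rescale `kon`. Occupancy is
read out both as the domain mean and at probe voxels (the first release
sites in placement order, deterministic given the seed).

**Initialisation.** Fields start at the mean-field steady state
`C* = flux·Km/(Vmax−flux)` of the volumetric release flux
`flux = Q_conc·f·R·density·v_voxel` (zero when the flux exceeds capacity),
and occupancy at its local equilibrium. Burn-in therefore only has to
build the heterogeneous spatial structure; 5 s of burn-in (concentration
relaxation ~Km/Vmax ≈ 35–105 ms; the slowest mode is D2 occupancy at
τ = 5 s, which starts equilibrated) precedes all statistics.

**Statistics.** "Tonic" is the 50th and "peak" the 99.5th percentile of
the pooled voxel distribution; focality is their ratio. Percentile curves
are computed per snapshot (default every 10 ms) over all voxels and
averaged over post-burn-in snapshots — under stationarity this estimates
the space-and-time-pooled quantiles with negligible bias and bounded
memory. The spatial mean is reported pooled over space and post-burn-in
time (the per-millisecond trace is also recorded, so a time-resolved mean
is always available).

## Named experiments and desk-scale sizes

All headline runs use a 50 µm cubic domain (the smallest size that
faithfully mimics larger simulations; 100 µm is available) at 1 µm voxels.

* **Pacemaker runs** (DS/VS): 10–12 s simulated, statistics after 5 s.
* **Pause**: 10 s equilibration, 1 s complete silence of all neurons,
  1–2 s recovery. The headline value is the *domain-mean* D2 occupancy at
  pause end (the probe-site mean runs ≈0.05 higher and is also recorded).
* **Bursts**: every active site inside a central 10×10×10 µm cube receives
  the pulse train (3/10 Hz, 6/20 Hz, 12/40 Hz) on top of tonic firing.
  Per-pulse release probability defaults to 1.0 — synchronous, locally
  induced release; with the tonic 6 % the released mass is an order of
  magnitude too small to produce any appreciable spill-over (see
  Limitations). Spill-over = volume above 100 nM at the last pulse (and
  +100 ms), divided by the 1000 µm³ cube.
* **Sweeps**: one-parameter grids over Vmax, Km, quantal size, release
  probability, firing rate, or active site fraction (the latter at one
  site per 9 µm³). Sweeps default to a 20 µm domain and 6–8 s with common
  random numbers across grid points; the Km sweep also reports values
  normalised to the region default (the competitive-inhibition read-out).
* **Granularity check**: matched runs at 0.5 and 1 µm voxels in a 25 µm
  domain; the headline number is the median |relative| percentile
  deviation over percentiles 5–99. Deviations concentrate in the upper
  tail, where near-source discretisation dominates.
* **FSCV trains**: 120 pulses at 10/30/60 Hz delivered to every neuron
  (field stimulation), region-mean trace box-averaged to the 100 ms scan
  grid and convolved with the unit-sum desorption kernel. Normalising the
  kernel makes steady concentrations read out unchanged; it affects only
  the absolute gain, not DS/VS comparisons.

## Varicosity nanocluster sub-model

A 1.5 µm × 800 nm ellipsoidal varicosity is unfolded to a 1.8 µm square
membrane; the box above is 3.52 µm tall so the extracellular volume is
seven times the varicosity volume. Transporter capacity lives in the
membrane-adjacent voxel layer only — dispersed, or as eight non-overlapping
disks of 20–160 nm diameter rasterised by sub-voxel area overlap (5×5
supersampling). The volume-mean capacity is exactly 4 µM/s in every layout
(conserved to 1e-12), so scenarios differ only in where the capacity sits.
Lateral boundaries wrap (the unfolded membrane is closed); top and bottom
reflect. The drive protocol adds dopamine uniformly at the space-averaged
quantal rate (≈228 nM/s from the release components); the clearance
protocol starts from a uniform 100 nM load.

The native grain is 20 nm with `dt` just below the stability bound
(0.9 × dx²/(6 Da) = 1.86e-7 s). Desk-scale runs use a 40 nm grain with the
correspondingly ×4 step; this preserves the dispersed steady state, the
clearance times and their strict ordering across cluster sizes, but
inflates the effective absorber radius of sub-grid (20 nm) clusters, which
damps the concentration rise after switching to the densest layout (~20 nM
at 40 nm versus ~30 nM at the native grain; see Limitations).

## Localisation clustering

`percent_clustered` is DBSCAN (scikit-learn) with an explicit neighbourhood
*radius* — the imaging literature quotes this parameter sometimes as a
radius, sometimes as a diameter, so the API never says "size". The
statistic (share of non-noise localisations) is independent of DBSCAN's
order-dependent border-point tie-breaking, and the tests verify it against
an O(n²) neighbour-graph reference. Region comparisons use Welch's
unequal-variance t-test with images as the unit of analysis. The synthetic
generator produces isotropic Gaussian clusters over a
complete-spatial-randomness background with ground-truth labels; it
emulates clustered-plus-background point patterns but not detector noise,
drift, multiple blinking of single fluorophores, or localisation precision
broadening — recovery tests on it validate the pipeline's arithmetic, not
its robustness to those artefacts.

## What the synthetic conditions do and do not show

The tissue generator realises the study conditions (Table-1-style DS
parameters and the VS modifications) with homogeneous, uncorrelated
Poisson firing and uniform site placement. Real striatum has spatially
correlated firing, heterogeneous innervation density, and autoreceptor
feedback; passing tests show the solver and statistics are correct under
the stated model, not that the model captures those features.

## Numerical choices

* Explicit Euler only; no implicit/ADI solvers, no adaptive stepping, no
  non-periodic boundaries (out of scope by design).
* Uptake-then-diffusion within a step, applied sequentially (not
  Jacobi-style from the same pre-step field); a test pins the fused numba
  engine bitwise to the composed public operators.
* Percentile quantisation: percentile grid 0.5 %–99.9 % in 0.5 % steps.
* Fractional site counts are resolved binomially; site collisions are
  avoided by sampling voxels without replacement.
* Degenerate inputs: zero-length pauses, zero-pulse bursts and zero
  density are valid and reduce to the pacemaker baseline; flux ≥ capacity
  makes the mean-field initial condition fall back to zero.
* All statistics are bit-for-bit reproducible for a fixed seed; a single
  integer seed spawns the four RNG streams.

## Limitations

* **Burst spill-over magnitudes.** With synchronous per-pulse release the
  model reproduces the qualitative burst phenomenology (3 AP/10 Hz is
  indistinguishable from baseline; the 12 AP/40 Hz spill-over is ~3.3×
  the 6 AP/20 Hz one) but the absolute volume-above-100 nM ratios are
  ~2.4× and ~8× the cube volume, several-fold below published estimates of
  10×/30×. Total released mass bounds the achievable ratio, so larger
  values would require multivesicular release or weaker effective uptake
  during bursts; both are exposed as parameters
  (`BurstSegment.release_probability`, region overrides) rather than
  baked in.
* **Sub-grid nanoclusters at desk scale.** At the 40 nm grain a 20 nm
  cluster cannot be represented smaller than one voxel; steady-state
  elevation after clustering is therefore underestimated (~20 vs ~30 nM).
  The native 20 nm grain is implemented and exact but needs hours, not
  minutes.
* D2 pacemaker occupancy at release-site probes time-averages ≈0.63, about
  0.08 above the ~0.55 level a representative trace suggests: each quantal
  event in the probe's own voxel kicks occupancy up by ~0.3·(1−occ) during
  the event's sub-millisecond residence, and the slow koff integrates the
  kicks. The between-kick baseline and the domain mean both sit at
  0.55–0.57.
* No electrochemistry beyond the printed FSCV impulse response; no
  receptor desensitisation or downstream signalling; no raw dSTORM
  fitting or drift correction.
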