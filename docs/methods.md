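# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each pipeline stage.  Units throughout: coordinates in
nm (origin bottom-left, y up), time in s, diffusion in µm²/s; frames are
0-based; images are rasterized row-major with a stated nm/pixel and
pixel-centre convention.

## Synthetic ground truth

Every analysis stage is validated against data from `efferoquant.synthetic`,
whose generators emulate the *statistical* structure of the corresponding
experiments.  All randomness flows from a single seeded
`numpy.random.Generator` per call; fixed seeds give bit-identical outputs.

**Point patterns.** Two species over a square field (default 10×10 µm) in
three regimes: `csr` (each species an independent homogeneous Poisson
process), `coclustered` (both species uniform inside shared disks, default
diameter 120 nm — the scale of receptor nanoclusters), and `contacting`
(each species in its own disk, the pair separated edge-to-edge by
`contact_gap_nm`).  Default density is 0.4 molecules/µm² per species (one
label per 2.5 µm², the sparse-labeling regime of single-particle work);
cluster occupancy defaults to 10 molecules per species.  Localization jitter
is isotropic Gaussian; the default sd of 20 nm is a package choice matching
~20 nm-resolution localization microscopy and is always echoed into the
table's `precision_nm` column rather than assumed downstream.

**Bleach traces.** Each of `n_steps` fluorophores survives a geometric
number of frames (per-frame bleaching probability, default 0.01 at 100 ms
frames — full bleaching of a 28-mer in ~40 s) and then goes dark
irreversibly; additive Gaussian noise and a constant baseline complete the
trace.  The geometric schedule means two fluorophores *can* bleach in the
same frame — a realistic property that the counting method must survive
(see below).  No blinking or photophysical state kinetics are modelled.

**FRET stacks.** The forward model is the exact algebraic inverse of the
estimator (documented side by side with it in `fret.py` /
`synthetic.FretForwardSpec`): with acceptor map A, donor map D and true
efficiency E,

    Iaa = A
    Idd = D(1−E) + αA
    Ida = βD(1−E) + γA + EA

plus per-channel background and Gaussian noise, so that
F_c = Ida − β(Idd − αIaa) − γIaa = E·Iaa exactly.  This is an algebraic
inverse, not a photophysics model: quenching is applied uniformly through E
and the sensitized term is expressed relative to the acceptor signal
because E_A is the acceptor-normalized apparent efficiency.  All FRET
round-trip tests are therefore self-consistent by construction, which is
the point: they verify the estimator's algebra and noise behaviour, not the
spectroscopy.

**Trajectories.** Brownian: Gaussian increments with variance 2·D·dt per
axis.  Confined: the same increments with specular (billiard) reflection at
a circular corral — each straight step is reflected across the tangent at
every boundary crossing, which preserves the uniform measure on the disk
and hence gives the textbook long-lag MSD plateau of diameter²/4.  (A
simpler radial fold-back was tried first and rejected: it is not
measure-preserving when the step size is comparable to the corral, and
compresses the stationary distribution.)  Directed: Brownian plus constant
drift.  Localization error is added per position.  Defaults — D = 0.1
µm²/s, corral 200 nm, drift 1 µm/s, 100 ms frames, 20 nm error — are
typical membrane-receptor values and define the regime in which the
classifier's operating points (below) were fixed.

**Uptake scenes.** Disk-shaped cells on a grid, disk-shaped targets placed
without overlap; a separate "outside" channel marks only non-internalized
targets (emulating surface labeling of what remains accessible from the
medium), and an optional dye channel carries tracer signal for every
target.  Ground truth (per-cell counts, per-target masks, expected index)
is attached for exact verification.

What passing tests on these generators does **not** show: robustness to
drift, chromatic misregistration, detection/linking errors, anisotropic
localization error, camera noise statistics, or 3-D effects.  The pipelines
assume those have been handled upstream.

## SMLM co-clustering statistics

G(r) is computed per annulus as (target count)/(n_ref · annulus area · mean
target density), with **border-exclusion** edge correction: reference
molecules closer than r_max to the ROI boundary are dropped, so every
counted annulus lies fully inside the ROI.  Border exclusion was chosen
over toroidal wrapping (only valid for periodic synthetic fields) and
Ripley-style isotropic correction (heavier, and unnecessary at these field
sizes).  Annuli are half-open (lo, hi] so the KD-tree implementation
(`cKDTree.count_neighbors` at the bin edges) and the brute-force pairwise
oracle used in tests count identically — the convention matters only on a
measure-zero set for continuous data.  Default bins: 10 nm width, 0–500 nm,
bracketing the 120–300 nm cluster length scales; raw G(r) scales with
density, so a min–max scaled curve is always carried alongside.

The randomization envelope is the pointwise 2.5th/97.5th percentile of
G(r) over re-draws of the reference species uniform over the ROI (the
Monte-Carlo model of non-interacting proteins); percentiles are used rather
than a parametric interval for distribution-freeness.  At least 20
replicates are required; 100 is the default.

Clusters are extracted with OPTICS using reachability-threshold (ξ-free,
DBSCAN-equivalent) extraction at `max_reach_nm` (default 60 nm) and minimum
membership `min_points` (default 10); the cluster boundary is the convex
hull (alpha-shapes were rejected to avoid an extra shape parameter) and the
diameter is the maximum pairwise member distance.  Relation classification
is mutually exclusive and evaluated in order: *colocalized* if at least
`intermix_frac` (default 0.5) of a cluster's molecules fall inside some
partner hull; else *contacting* if the hull-to-hull distance is at most
`contact_dist_nm` (default 20 nm ≈ localization precision); else *neither*.
Both thresholds are config-exposed and echoed into output metadata.  Note
that convex hulls of sparsely occupied clusters undershoot the true disk
edge, so detecting "contacting" pairs at low occupancy needs either higher
occupancy or a wider contact distance; the defaults are tuned for
cluster occupancies of tens of molecules.

## Stepwise-photobleaching counting

Step detection is greedy binary segmentation: change points are inserted
where they most reduce the residual sum of squares until the best remaining
gain falls below `penalty · σ² · log n`, with σ estimated robustly from the
median absolute successive difference (floored at 10⁻⁶ of the dynamic range
so floating-point cancellation on noiseless traces cannot masquerade as
signal).  Upward transitions — blinking or late arrivals — are merged into
neighbouring plateaus: the counting model assumes monotone bleaching.
`detect_steps` defaults to penalty 3 (parsimonious staircases, idempotent
on its own fit); `count_molecules` segments with penalty 2, because for
counting, over-segmentation is harmless (a spurious split creates two
plateaus at the *same* lattice level) while a missed short plateau
contaminates its neighbour's mean.

Counting is deliberately not "number of change points": with a geometric
bleach schedule two fluorophores can share a frame, so a transition can
span several units.  Instead:

1. **Clean plateaus.** Only plateaus of ≥ 3 frames (plus the first and the
   final, baseline plateau) enter the unit fit — merging can only shorten
   undetected plateaus, so longer plateaus have uncontaminated means.
2. **Lattice unit.** The per-fluorophore unit u is found by period
   estimation: a dense geometric grid of candidates (plus the observed
   transition sizes and small integer fractions of them, which matter on
   near-noiseless traces) is scored by the noise-normalized squared
   residual of every clean level to its nearest integer multiple of u,
   capped at 3σ to tolerate occasional mixture outliers.  Levels alone
   cannot reject the half-unit sub-lattice (u/2 fits any set of u-multiples
   exactly, and equal-length plateau mixtures even produce exact
   half-multiples), so the score adds a prior of 2 units per *extra*
   molecule implied by a transition's multiplicity — single bleach events
   dominate under a geometric schedule, and the prior doubles under the
   sub-lattice.  The winner is refined by iteratively reweighted least
   squares of level against lattice index through the origin.
3. **Count.** The molecule count is the first plateau's lattice index,
   `round((L₀ − baseline)/u)`.  Frame 0 is always pre-bleach, so its
   lattice index anchors the count; if the full first-plateau mean
   disagrees with it (a missed first bleach event), the longest prefix
   consistent with the frame-0 index is used.

Counts up to the direct-count limit (default 28, the reliability bound for
direct counting) are reported as `direct_count`; larger clusters as
`regression_extrapolation` — the same initial-amplitude-over-unit quantity,
with the ordinary final-window regression (`unit_intensity`, default window
15 steps; the literature describes the window variously as the final 10–15
or 15–20 steps, so it is configurable 10–20 and echoed into metadata)
reported alongside for QC.  A trace whose final plateau sits more than
2σ + u/2 above baseline raises `UnbleachedTraceError` rather than returning
a partial count.

At the reference conditions (noise sd = 0.2 × unit, 50 seeds per count)
exact recovery stays ≥ 90% for every true count from 1 through 35.

## Sensitized-emission FRET

Coefficients are medians of the defining channel ratios over
above-background pixels of single-label controls (median-of-ratios resists
bright debris): β = Ida/Idd on donor-only cells, α = Idd/Iaa and
γ = Ida/Iaa on acceptor-only cells; backgrounds are per-channel medians of
unstained cells.  δ (Idd/Ida on acceptor-only cells) is measured for QC
but, by its own definition, equals α/γ identically and carries no
independent information; it does not enter the E_A formula.

E_A = F_c/Iaa with F_c = Ida − β(Idd − αIaa) − γIaa, computed on
background-subtracted channels clamped at zero.  Pixels whose acceptor
signal is below a floor (default 3× the acceptor background sd) are
undefined — the division is meaningless there.  The map is clamped to
[0, 0.3136], the maximum theoretical efficiency of the FITC /
octadecyl-rhodamine B pair (used as a clamp constant, not recomputed);
regional *means* should be computed with `clamp=False`, because folding
per-pixel noise at the physical bounds biases the average.  The validity
mask is Otsu(Iaa) AND Otsu(Idd), dilated once with a 3×3 structuring
element.  The display conversion inverts polarity (high = activation, since
activation extends the integrin away from the membrane acceptor and lowers
E_A) and is monotone decreasing in E_A by construction.

## Diffusion and motion classification

Quality filters: tracks with mean localization precision worse than 25 nm
or fewer than 20 frames are dropped, with per-criterion counts reported.
The MSD is time-averaged over all same-lag pairs; D is the slope/4 of an
OLS line over the first 4 lags with a free intercept (the intercept absorbs
the static 4σ² localization-error offset, so no moment deconvolution is
attempted).

The MSS uses moments ρ = 1..4 with γ_ρ fit on log–log axes over lags up to
1/10 of the track length — short-lag emphasis, where displacement pairs are
most numerous and least correlated; longer windows (e.g. 1/4 of the track)
were measured to inflate the per-track slope spread by ~40% on Brownian
ensembles without improving the mean.  The MSS slope is fit through the
origin (γ₀ = 0 analytically; an unconstrained fit is available).  Class
boundaries are confined < 0.35 ≤ free ≤ 0.6 < directed: operating points,
not theory — finite Brownian tracks with localization error give empirical
slopes of 0.48 ± 0.06 at 100 frames, so the free band is asymmetric around
the ideal 0.5.  At the reference conditions each class is recognized with
≥ 90% per-class accuracy; both thresholds are config-exposed.

The confinement-zone diameter is an interpretation, pinned as: project
positions on the major eigenvector of the positional variance–covariance
matrix; take the 90th percentile of pairwise projected distances; divide by
0.5876, the same percentile for points uniform in a disk in units of the
disk diameter (evaluated numerically from the semicircle projection
marginal at 4×10⁶ samples).  Localization error inflates the apparent
spread as sqrt(d² + 16σ²); the estimate is deconvolved accordingly using
the track's reported precision.  On 200 nm corral simulations the mean
estimate is within ~5% of truth.  Strong confinement (positions near
equilibrium within one frame) is assumed; for marginally confined tracks
the positions are not yet uniform over the corral and the estimate will
undershoot.

## Morphometry

Feret's diameter is the exact maximum pairwise distance over convex-hull
vertices.  Synapse expansion normalizes each time point's diameter to the
first *visible* outline — operationalized as the first outline whose area
exceeds a configurable floor, since the original visibility criterion
(being in the bilayer's focal plane) is not recoverable from 2-D outlines.
Radial profiles bin pixels by centre distance, so per-annulus means exactly
conserve the image total.  Cup profiles sample channel and membrane
reference along the base→tip axis, divide (correcting for membrane
density), min–max scale to [0, 1], and reject cups outside the 50–75%
engulfment window; a ratio with no dynamic range is flagged flat rather
than scaled.  In the uptake index, a bead is *bound* when ≥ 50% of its
footprint carries outside-label signal (partial-engulfment scoring is not
standardized; the 50% overlap rule is a declared choice, configurable), and
apoptotic-cell mode integrates the tracer dye under the inverted Otsu mask
of the outside label, normalized to the control-group mean when provided.

## Problem sizes used in validation

Step-count reliability: counts 1–35 × 50 traces.  G(r) oracle equivalence:
20 instances ≤ 500 points.  Envelope calibration: 5000 points per species,
100 randomizations.  Diffusion recovery and classification: 200 tracks ×
100 frames per motion class.  These sizes give comfortable statistical
margins for every asserted tolerance while keeping the full suite around
half a minute.
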