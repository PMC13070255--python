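# efferoquant

Quantitative image-analysis pipelines for efferocytosis biology — the
engulfment of apoptotic cells by macrophages — built around the measurements
used to characterize the **efferocytic synapse**: the ordered contact zone in
which the receptor MERTK and its β₂-integrin co-receptors cluster, activate
and drive engulfment.

The package implements five analysis stages, each exercisable end-to-end on
synthetic data with known ground truth:

| Stage | Module | What it measures |
|---|---|---|
| SMLM co-clustering | `efferoquant.smlm` | cross-species radial distribution G(r) with Monte-Carlo randomization envelopes; OPTICS cluster extraction; colocalized / contacting / neither cluster-relation fractions |
| Molecular counting | `efferoquant.photobleach` | molecules per cluster from stepwise-photobleaching traces, with regression extrapolation for clusters beyond the reliable direct-count limit (28 steps) |
| Integrin activation | `efferoquant.fret` | corrected sensitized-emission FRET (bleed-through coefficients α, β, γ, δ from single-label controls; pixelwise E_A with Otsu AND masking, clamped at the FITC/ORB bound 0.3136) |
| Membrane diffusion | `efferoquant.spt` | per-trajectory diffusion coefficients, moment-scaling-spectrum motion classes (free / confined / directed) and confinement-zone diameters |
| Morphometry | `efferoquant.morphometry` | Feret's-diameter synapse expansion, Pearson colocalization, radial profiles, base-to-leading-edge cup profiles, phagocytic/efferocytic index |
| Ground truth | `efferoquant.synthetic` | seeded generators for every input above |

## The statistics at the core

**Radial distribution.** For reference species R and target species T,
G(r) is the density of T in the annulus (r, r+dr] around an R molecule,
normalized to the mean density of T over the ROI: G ≈ 1 for non-interacting
species, G ≫ 1 at r below a cluster diameter for co-clustering, and a
secondary peak at one–two diameters for clusters that touch without
intermixing.  Significance is assessed against a pointwise 95% envelope of
G(r) under positional randomization of R over the same area.

**Stepwise photobleaching.** Under continuous maximum-power excitation a
cluster's background-subtracted intensity is a descending staircase; the
per-fluorophore unit intensity u is found by integer-lattice fitting of the
plateau levels, and the molecule count is the number of unit steps from the
initial plateau to baseline.  Clusters beyond the 28-step direct-count limit
are counted as (initial intensity)/u, with u from an ordinary least-squares
regression over the final plateaus.

**Sensitized-emission FRET.** With donor/FRET/acceptor channels Idd, Ida,
Iaa and control-derived coefficients, the corrected sensitized emission is
F_c = Ida − β·(Idd − α·Iaa) − γ·Iaa and the apparent efficiency
E_A = F_c / Iaa.  Inactive (bent) β₂ integrin FRETs strongly to a membrane
acceptor; activation extends the receptor and *decreases* E_A.

**Moment scaling spectrum.** The displacement moments μ_ρ(τ) ∝ τ^γ_ρ for
ρ = 1..4; the slope of γ_ρ versus ρ is ≈ 0.5 for Brownian motion, < 0.5 for
confined and > 0.5 for directed motion.  D comes from the initial MSD slope
(free intercept absorbing localization error), and the confinement-zone
diameter from the 90th percentile of pairwise projected extents along the
positional-covariance major axis.

## Worked example

```python
import numpy as np
from efferoquant import synthetic as syn, photobleach, smlm, spt

# 1. count molecules in a synthetic 24-fluorophore cluster trace
trace, truth = syn.gen_bleach_trace(syn.TraceSpec(
    n_steps=24, unit_intensity=100.0, noise_sd=20.0, seed=42))
fit = photobleach.count_molecules(trace)
print(f"true steps: 24  counted: {fit.molecule_count} ({fit.method})  "
      f"unit intensity: {fit.unit_intensity:.1f}")

# 2. co-clustering: G(r) on a co-clustered two-species pattern
spec = syn.PatternSpec(mode="coclustered", n_clusters=25, seed=42)
table, _ = syn.gen_point_pattern(spec)
roi = syn.field_roi(spec)
a, b = table[table.species == "A"], table[table.species == "B"]
rd = smlm.radial_distribution(a, b, smlm.default_bins(), roi)
low, high = smlm.mc_envelope(a, b, smlm.default_bins(), roi, n_reps=50, seed=42)
peak = np.argmax(rd.g)
print(f"G(r) peak at r = {rd.r_mid_nm[peak]:.0f} nm, G = {rd.g[peak]:.1f} "
      f"(envelope high there: {high[peak]:.2f})")

# 3. diffusion: classify a confined ensemble
tracks, _ = syn.gen_trajectories(syn.MotionSpec(
    model="confined", corral_diameter_nm=200, n_tracks=100,
    track_length=100, seed=42))
summary = spt.fraction_confined(spt.analyze_tracks(tracks))
print(f"confined fraction: {summary.fraction_confined.iloc[0]:.2f}, "
      f"mean confinement diameter: {summary.mean_confinement_nm.iloc[0]:.0f} nm")
```

Output:

```
true steps: 24  counted: 24 (direct_count)  unit intensity: 100.0
G(r) peak at r = 35 nm, G = 195.6 (envelope high there: 5.10)
confined fraction: 1.00, mean confinement diameter: 210 nm
```

The counted staircase matches the generator exactly; the co-clustered
pattern is ~40-fold enriched over its own randomization envelope at short
range (clusters of 120 nm diameter produce the peak well below 100 nm); and
the 200 nm corral ensemble is classified fully confined with the diameter
recovered within ~5%.

There is also a CLI for shell-driven runs, mirroring the library:

```bash
efferoquant simulate tracks --seed 2 --out sim/
efferoquant spt --tracks sim/trajectories.csv --out results/
efferoquant smlm gr --reference ref.csv --target tgt.csv --roi roi.geojson
```

Every run writes a `provenance.json` (parameters, seed, input checksums)
sufficient to reproduce deterministic stages bit-identically.

## Limitations

The synthetic generators emulate the statistical structure of the real
assays, not their optics: no photophysical blinking, no drift, no camera
noise beyond additive Gaussian, 2-D only.  Particle detection/linking and
super-resolution reconstruction are out of scope — the pipelines consume
coordinate tables, trajectories and registered image stacks.  See
`docs/methods.md` for the model assumptions, parameter defaults and design
choices.
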