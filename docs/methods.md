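# Methods

## Surface model and lever placement

The sensor surface is a square of side L tiled by flat-topped hexagons of
in-radius r (default 2.5 nm). Hexagon centers form a triangular lattice with
spacing 2r: rows run along x with pitch r√3 and alternate rows offset by r;
the origin center sits at (r, r). Centers strictly inside the square are
kept; partial boundary hexagons are dropped (the simplest consistent rule —
boundary effects are instead controlled by surface size, below). Lattice
orientation and offset are arbitrary in principle; placement statistics are
translation-equivariant, which the test suite checks directly.

A target *mean* inter-lever distance d is realized by occupying each hexagon
independently with probability p = (2r/d)² (clamped to 1), the ratio of the
tiling-hexagon area to that of a hexagon of in-radius d/2. Two consequences
matter for interpretation:

- **"Mean distance" is an area-ratio convention**, i.e. one lever per
  hexagon of in-radius d/2 on average — *not* the mean nearest-neighbor
  distance, which is numerically different (for a sparse random pattern of
  density λ = 1/(2√3(d/2)²), the mean nearest-neighbor distance is
  ≈ 0.5/√λ ≈ 0.47·d).
- The lattice enforces a hard minimum spacing of 2r = 5 nm between levers in
  every realization, reflecting DNA radius and electrostatic repulsion.

## Binder reach

A binder bridges two levers when their anchor-to-anchor distance (Euclidean,
in the surface plane) does not exceed

    reach = 2·lever_length + her2_terms·her2_length + span.

Levers are treated as freely pivoting tethers with no excluded volume.
Defaults: lever 32 nm, HER2 ectodomain 8 nm, `her2_terms = 2`. Counting the
ectodomain twice — once per bridged lever — is the physically consistent
reading, since each bridged lever carries one HER2 between lever tip and
paratope; `her2_terms = 1` is exposed for sensitivity analysis. Presets:
"441" span 20 nm (reach 100 nm), "mAb_combo" span 14 nm (94 nm), "841" span
2 nm (82 nm). Valency enters only through span: a molecule bridges at most
two levers regardless of its number of paratopes.

## Sequential saturation

Each lever starts with two free binding sites (two epitopes on its HER2).
Molecules are introduced one at a time until no free site remains; each
iteration consumes at least one site, so termination is guaranteed. Per
molecule:

1. The initial lever is drawn uniformly among levers with ≥ 1 free site
   (default) or uniformly among free sites (`initial_draw="sites"`), and one
   of its sites is consumed.
2. The molecule then binds the closest *other* lever with a free site within
   reach, consuming a site there and recording a bridge; equidistant
   candidates resolve to the lowest lever index (a measure-zero tie-break
   that keeps runs deterministic). If no lever is reachable the molecule
   stays singly bound.

Nothing prevents a second molecule from bridging an already-bridged pair;
the bridge *set* (unordered lever pairs) is what the interlinking metric
consumes. The interlinked fraction is the number of levers incident to at
least one bridge divided by the lever count; chains count every member.

The initial draw is pinned to the uniform stream by the contract
`a = sorted_eligible[floor(u·|eligible|)]`, which lets an independent
brute-force replay (full distance matrix, literal rules) verify the
optimized simulator (kd-tree neighbor lists, precomputed per surface)
bridge-for-bridge on small instances.

Replication: each condition runs `n_surfaces` independent placements × 
`n_repeats` independent binding orders (default 10 × 10 = 100 replicates);
mean and SD are reported over all replicates. The default surface side is
max(2.4 µm, 12·(d + reach)) with open boundaries, which keeps the boundary
strip a small perimeter fraction; doubling the side at d = 200 nm moves the
mean fraction by well under 2 percentage points (tested).

All seeds derive from a single base seed via `numpy.random.SeedSequence`
spawn keys hashed from stage/surface/repeat labels, so replicates are
independent yet exactly reproducible, and derived seeds are recorded in run
manifests.

## Kinetics

Traces follow the 1:1 binding model (association
y = Y_eq(1 − e^(−k_obs·t)) with k_obs = k_on·c + k_off and
Y_eq = c/(c + K_D); dissociation y = y_end·e^(−k_off·t) starting from the
noiseless association end level) with additive i.i.d. Gaussian noise.
Photon-counting noise is out of scope. Defaults mirror the modelled
experiment: 20 nM analyte, 5 min association, 60 min dissociation, 300
points per phase.

Fitting is nonlinear least squares (`scipy.optimize.curve_fit`, non-negative
amplitude/rate bounds) of Σᵢ Aᵢe^(−kᵢt) (dissociation) or
Σᵢ Aᵢ(1 − e^(−k_obs,i·t)) (association). Initial guesses come from the
log-linearized tail slope (decay) or the 63%-rise time (association); on
non-convergence up to five log-normally jittered restarts are tried, and a
fit that still fails returns a flagged result rather than NaNs. A constant
dissociation trace short-circuits to a degenerate zero-amplitude result.
The offset term defaults to off, since normalized, blank-referenced traces
are baseline-corrected; a flag enables it.

Biphasic rates are reported descending; k_off (and the k_obs used for
k_on) is the dominant-amplitude rate. k_on = (k_obs − k_off)/c requires
k_obs > k_off; violations are flagged as invalid kinetics. Phase-count
selection uses AICc (Gaussian likelihood, σ counted as a parameter): the
biphasic model is kept only when its AICc improves on the monophasic one by
more than 2, with ties going to parsimony.

At the default conditions with 1% noise, the median recovered k_on, k_off
and K_D over 50 seeds sit within ~1% of truth (the acceptance suite asserts
5%); noiseless traces are recovered to better than 10⁻³ relative.

## Immobile fraction

The simulator emulates sparse single-particle tracking: n particles start
uniformly in the field; mobile ones take per-axis Gaussian steps of sd
√(2·D·dt) per frame, immobile ones are static; every position is blurred by
Gaussian localization noise of sd `precision`. Localizations outside the
field are discarded (truncation) rather than reflected or clipped — clipping
would pile localizations on the boundary and fabricate immobile clusters.
Defaults: D = 0.1 µm²/s, dt = 30 ms, 100 frames, precision 20 nm, field
20 × 20 µm. The field size puts 200 particles at 0.5 particles/µm², the
sparsity regime tracking experiments are designed for; at substantially
higher densities mobile tracks cross and chain into spurious dense clusters,
and the classifier (like any pooled-localization method) degrades.

The estimator clusters pooled (x, y) localizations with DBSCAN
(eps = 3 × precision by default, min_samples = 10) and calls a cluster an
immobile particle iff it has ≥ min_samples localizations spanning
≥ min_frame_span (default 10) distinct frames. The temporal criterion is the
minimal adaptation that distinguishes a parked emitter from a transiently
dense passage of a mobile one; with min_frame_span = 1 the classifier
reduces to plain density clustering. Two conventions are reported:

- **per-particle** (headline): with ground-truth identities, the fraction of
  particles whose localizations fall predominantly (> 50%) in immobile
  clusters, over the true particle count; without identities, immobile
  clusters divided by (immobile clusters + estimated mobile-track count,
  the non-clustered localizations divided by the number of distinct frames).
- **per-localization**: immobile-cluster localizations over all
  localizations. This runs higher than the per-particle value because
  immobile particles contribute complete, fully clustered piles.

What the simulation does not emulate: blinking/photobleaching (every
particle is localized every frame it is in the field), detection dropouts,
anisotropic or anomalous diffusion, and localization-precision
heterogeneity. Passing recovery tests therefore demonstrates the classifier
logic, not robustness to every artifact of real SMLM data.

## Problem sizes

Simulation scales used throughout tests and examples are the study's own:
10 × 10 replicates per crosslinking condition on surfaces of side
max(2.4 µm, 12·(d + reach)); 300-point traces; 200-particle, 100-frame
localization sets. A full 3-binder × 3-distance sweep takes ~10 s on one
core; the whole test suite runs in well under a minute plus ~30 s of
full-scale acceptance checks.
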