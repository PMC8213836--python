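# leverxlink

Computational companions to biosensor and single-molecule experiments on
multivalent anti-HER2 binders, as a reusable Python library:

1. **Nanolever crosslinking Monte Carlo** — a stochastic-geometry simulation
   of a switchSENSE-style sensor surface: DNA nanolevers (32 nm) carrying
   HER2 ectodomains (~8 nm) are placed on a hexagonally tessellated square so
   that a target mean inter-lever distance *d* ∈ {50, 100, 200} nm is
   realized, then saturated one molecule at a time by bivalent or tetravalent
   binders that bridge any two levers whose anchors lie within the binder's
   reach. The readout is the fraction of levers *interlinked* (incident to at
   least one bridging molecule).
2. **Binding-kinetics fitting** — simulation and mono-/biphasic exponential
   fitting of fluorescence-proximity binding traces under the 1:1 model
   *y*(t) = Y_eq(1 − e^(−k_obs·t)) with k_obs = k_on·c + k_off, yielding
   k_on, k_off and K_D = k_off/k_on from an association/dissociation pair.
3. **Immobile-fraction estimation** — a temporal-persistence DBSCAN
   classifier for single-molecule localization data: a dense localization
   cluster counts as an immobile receptor only if it persists over at least
   `min_frame_span` distinct frames, separating parked receptors from
   transiently dense passages of diffusing ones.

All inputs are generated in-package; a CSV dialect is documented for each
stage so real trace or localization data can be analyzed too.

## The crosslinking model

The square surface is tiled with hexagons of in-radius r = 2.5 nm, whose
centers form a triangular lattice of spacing 2r = 5 nm — the physical
minimum lever separation. Each hexagon holds a lever with probability
p = (2r/d)², the area ratio of the tiling hexagon to one of in-radius d/2,
so on average one lever falls per hexagon of in-radius d/2. A binder with
paratope span s bridges anchors up to

    reach = 2·32 nm (levers) + 2·8 nm (HER2 ectodomains) + s

apart: 100 nm for the tetravalent scFv–IgG fusion ("441", s ≈ 20 nm), 94 nm
for the two-mAb combination ("mAb_combo", s ≈ 14 nm) and 82 nm for the
bivalent scFv–Fab fusion ("841", s ≈ 2 nm). Each lever starts with two free
binding sites; molecules arrive sequentially, bind a uniformly random lever
with a free site, then bridge to the closest other lever with a free site
within reach (or stay singly bound), until no site remains.

## Worked example

```bash
python examples/crosslink_curve.py
```

```
     spec  mean_distance_nm  mean    sd   n
      441            50.000 0.990 0.002 100
      441           100.000 0.912 0.010 100
      441           200.000 0.538 0.029 100
      841            50.000 0.982 0.003 100
      841           100.000 0.830 0.017 100
      841           200.000 0.417 0.051 100
mAb_combo            50.000 0.989 0.002 100
mAb_combo           100.000 0.888 0.012 100
mAb_combo           200.000 0.513 0.033 100
```

Each row is the mean ± SD interlinked-lever fraction over 10 independently
placed surfaces × 10 binding orders. At high lever density every binder
bridges nearly everything; as the surface gets sparser the short-reach
bivalent binder (841) loses the most interlinking, while the tetravalent
binder still bridges ≈ 54% of levers at d = 200 nm.

The other examples follow the same pattern: `examples/single_surface.py`
dissects one saturation run, `examples/fit_kinetics.py` recovers
k_on = 1.01×10⁵ /M/s, k_off = 9.9×10⁻⁴ /s and K_D = 9.8 nM from a 1%-noise
trace simulated at the true values (10⁵, 10⁻³, 10 nM), and
`examples/immobile_fraction.py` recovers an immobile fraction of 0.600 from
a 60:40 immobile:mobile mixture of 200 simulated receptors.

A thin CLI mirrors the library:

```bash
lever-xlink curve --specs 441,841,mAb_combo --distances 50,100,200 \
    --surfaces 10 --repeats 10 --seed 1 --out results/
lever-xlink kinetics simulate --noise-sd 0.01 --out results/
lever-xlink immobile estimate --locs results/localizations.csv
```

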