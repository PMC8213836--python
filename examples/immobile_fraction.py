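"""Estimate the immobile receptor fraction from synthetic SMLM data.

Simulates 200 membrane receptors — 120 immobile, 80 diffusing at
0.1 um^2/s — imaged for 100 frames at 20 nm localization precision, then
recovers the immobile fraction with the temporal-persistence DBSCAN
classifier (a cluster counts as an immobile particle only if it is dense
AND persists across at least 10 distinct frames).
"""

from leverxlink import estimate_immobile_fraction, simulate_localizations

locs = simulate_localizations(n_mobile=80, n_immobile=120, D_um2_s=0.1,
                              precision_nm=20.0, n_frames=100, seed=1)
est = estimate_immobile_fraction(locs)  # eps = 3 x precision by default

print(f"localizations          : {len(locs)}")
print(f"immobile clusters found: {est.n_immobile} of {est.n_total} particles")
print(f"immobile fraction      : {est.immobile_fraction:.3f}  (truth 0.600)")
print(f"per-localization view  : {est.localization_fraction:.3f}")
print("\nThe per-particle fraction is the headline estimate; the "
      "per-localization fraction runs higher because immobile particles "
      "contribute denser, fully clustered localization piles.")
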