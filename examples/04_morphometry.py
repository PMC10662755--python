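"""Cycle placement within the islet: periphery and center distances.

The islet outline is a possibly non-convex alpha shape whose shrink factor
starts at 1/max(tau_beta, tau_alphadelta) and halves until a single polygon
results; shrink factor 0 would give the convex hull.
"""

from isletrings import analyze_islet, gen_ring_islet

res = analyze_islet(gen_ring_islet(n_ring=10, r_ring=12.0, seed=7))
m = res.morphometry
print(f"islet area (alpha-shape polygon): {m['islet_area']:.1f} square units")
print(f"shrink factor used: {m['shrink_factor']:.4f}")
for rec in m["cycles"]:
    print(
        f"cycle ({rec['direction']}): distance to periphery = "
        f"{rec['dist_periphery']:.2f}, to center = {rec['dist_center']:.2f}, "
        f"contains center = {rec['contains_center']}"
    )
# For a centered mantle ring the cycle runs along the islet outline
# (periphery distance ~0) while the centroid lies inside it.
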