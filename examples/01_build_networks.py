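"""Build capillary network geometries: named fixtures and random
planar networks with Horton-like diameter taper.

Run:  python examples/01_build_networks.py
"""

import numpy as np

from hemonet import NetworkSpec, build_fixture, discretize_walls, \
    generate_network

# a canonical test geometry: large feeder with a small side branch
side = build_fixture("side_branch", feeder_diameter=17.5, branch_diameter=6.0)
print(f"{side.name}: {len(side.segments)} segments, "
      f"{len(side.junctions)} junction(s)")
for s in side.segments.values():
    print(f"  segment {s.id}: d = {s.diameter:4.1f} um, "
          f"L = {s.arclength:5.1f} um")

# a random 3-generation network: bifurcating tree that reconverges
net = generate_network(NetworkSpec(generations=3, seed=1))
diam = [s.diameter for s in net.segments.values()]
print(f"\n{net.name}: {len(net.segments)} segments, "
      f"{len(net.junctions)} junctions")
print(f"  diameters {min(diam):.1f}-{max(diam):.1f} um "
      f"(physiological range is 5.5-24 um)")
by_gen = {}
for s in net.segments.values():
    if s.generation >= 0:
        by_gen.setdefault(s.generation, []).append(s.diameter)
means = [np.mean(by_gen[k]) for k in sorted(by_gen)]
print("  mean diameter per bifurcation generation:",
      [f"{m:.1f}" for m in means], "(non-increasing taper)")

# discretize the lumen boundary: closed polylines with outward normals
walls = discretize_walls(side, resolution=1.0)
print(f"\nwall discretization of {side.name}: "
      f"{sum(len(r) for r in walls.rings)} samples on "
      f"{len(walls.rings)} ring(s), total wall length "
      f"{walls.total_length():.0f} um")
# The wall length of the union of channel strips is what the immersed
# solver sees as the no-slip boundary.
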