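"""Per-focal neighborhood metrics for one hand-built plot.

A focal plant's neighborhood is every other plant in its plot.  Density
and conspecific proportion capture crowding; rarefied richness corrects
species counts for unequal plot occupancy; functional evenness (FEve) and
dispersion (FDis) summarize how neighbor growth strategies — SLA, wood
density, maximum height — fill trait space.
"""

import numpy as np

from revegrowth import (
    functional_dispersion,
    functional_evenness,
    neighbor_density,
    prop_intraspecific,
    rarefied_richness,
)

# a 200 m^2 plot holding 21 plants of four species; the focal is one of
# the 8 "acacia_a" individuals, so its neighborhood holds 20 plants
abundances = {"acacia_a": 7, "euc_b": 6, "euc_c": 4, "melaleuca_d": 3}
area_m2 = 200.0

# z-standardized (SLA, wood density, max height) per species
traits = np.array(
    [
        [0.8, 0.5, -1.0],   # acacia_a
        [-0.3, -0.4, 1.2],  # euc_b
        [-0.9, -0.2, 0.9],  # euc_c
        [0.4, 1.1, -0.8],   # melaleuca_d
    ]
)
counts = np.array(list(abundances.values()))

print(f"density:            {neighbor_density(21, area_m2):7.0f} plants/ha")
print(f"prop. conspecific:  {prop_intraspecific(abundances, 'acacia_a'):7.2f}")
print(f"rarefied richness:  {rarefied_richness(counts, n=9):7.2f} species per 9 neighbors")
print(f"FEve:               {functional_evenness(traits, counts):7.2f}")
print(f"FDis:               {functional_dispersion(traits, counts):7.2f}")
print()
print("A third of the neighbors share the focal's species; ~3.7 of the 4")
print("species would appear in a 9-plant subsample; FEve near 1 would mean")
print("evenly spread strategies, and FDis is the mean trait-space distance")
print("to the abundance-weighted centroid.")
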