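"""Wood-volume-weighted phylogenetic and functional diversity of a tree plot.

MPD is the abundance-weighted mean pairwise patristic distance, MNTD the
weighted mean distance to each species' nearest relative, and Rao's Q the
quadratic entropy of leaf-trait distances.
"""

import pandas as pd

from trophicweb import mntd, mpd, newick_from_string, patristic_distances, rao_q, trait_distances

tree = newick_from_string("((castanopsis:2,lithocarpus:2):1,(schima:1.5,elaeocarpus:1.5):1.5);")
dist = patristic_distances(tree)

species = ["castanopsis", "lithocarpus", "schima"]
wood_volume = [5.0, 1.0, 2.5]  # m^3, proxies for biomass dominance

print("MPD :", round(mpd(species, wood_volume, dist), 4))
print("MNTD:", round(mntd(species, wood_volume, dist), 4))

traits = pd.DataFrame(
    {
        "sla": [12.0, 14.5, 22.0, 19.0],
        "leaf_cn": [28.0, 31.0, 19.5, 22.0],
        "toughness": [2.1, 1.8, 1.1, 1.4],
    },
    index=["castanopsis", "lithocarpus", "schima", "elaeocarpus"],
)
td = trait_distances(traits)  # z-scored Euclidean / sqrt(n_traits)
print("RaoQ:", round(rao_q(species, wood_volume, td), 4))

# MPD weighs dominant species pairs most; Rao's Q is 0 for a monoculture
# and grows with both trait spread and volume evenness.
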