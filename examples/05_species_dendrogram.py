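"""Cross-species ortholog sharing and the Ward dendrogram.

Evolves an ancestral gene set down a planted clock-like tree with per-branch
loss, computes symmetrised Jaccard distances between the species gene sets
under identity orthology, and rebuilds the tree with Ward clustering.
"""

from exon5uc.evolution import same_topology, sharing_distance, ward_cluster
from exon5uc.simulate import SimulationConfig, simulate_species_sets

cfg = SimulationConfig(seed=5)
sets, ortholog_maps, planted = simulate_species_sets(cfg)

print("Retained gene-set sizes (ancestral pool: %d):" % cfg.pool_size)
for sp in sorted(sets):
    print(f"  {sp:<10} {len(sets[sp])}")

dist = sharing_distance(sets, ortholog_maps)
print("\nSharing distance matrix (1 - symmetrised Jaccard):")
print(dist.round(2).to_string())

dendrogram = ward_cluster(dist)
print("\nWard dendrogram (Newick):")
print(dendrogram.to_newick())
print("\nPlanted tree:")
print(planted)
print("\nTopology recovered:", same_topology(dendrogram.to_newick(), planted))
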