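"""Classify internal exons of a synthetic annotation by coding composition.

Builds a small annotation with planted exon classes, classifies every unique
internal exon, and prints the coding-type x splice-class count table. Type 2
("5UC") exons carry the translation initiation site; the Type2 x ASE cell is
the set of cassette exons whose skipping deletes the start codon.
"""

from exon5uc.classify import classify_all
from exon5uc.features import length_stats
from exon5uc.simulate import SimulationConfig, simulate_annotation

dataset = simulate_annotation(SimulationConfig(seed=1))
exons, summary = classify_all(dataset.genes)

print(f"{len(dataset.genes)} genes -> {len(exons)} unique internal exons\n")
print(summary.with_totals().to_string())
print(
    "\nEach row partitions one coding type over the four splice classes; "
    "the Type2/ASE cell counts the 5UC cassette exons."
)

stats = length_stats(exons)
print("\nMedian exon length (nt) per coding type:")
print(stats["median"].to_string())
print(
    "\nThe generator plants a larger length distribution for Type 2 exons, "
    "mirroring the size bias of initiation-site-containing exons."
)
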