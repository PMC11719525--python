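"""Junction-based PSI across tissues and the tissue-specificity statistic.

Simulates junction read counts around known inclusion levels, computes the
per-tissue PSI matrix with the read-count threshold, and summarises how far
each tissue deviates from an event's cross-tissue median (tissue-dPSI).
"""

from exon5uc.simulate import SimulationConfig, simulate_annotation, simulate_junction_counts
from exon5uc.splicing import (
    generate_se_events,
    moderate_fraction,
    tissue_delta_psi,
    tissue_psi_matrix,
)

dataset = simulate_annotation(SimulationConfig(seed=2))
samples, tissue_map = simulate_junction_counts(dataset)
events = generate_se_events(dataset.genes)

psi = tissue_psi_matrix(events, samples, tissue_map, min_total=50)
print(f"PSI matrix: {psi.shape[0]} events x {psi.shape[1]} tissues")
print(psi.head(3).round(3).to_string())

dpsi = tissue_delta_psi(psi)
print("\nMedian |tissue-dPSI| per tissue (higher = more tissue-specific):")
print(dpsi.abs().median().sort_values(ascending=False).round(3).to_string())
print(
    "\nThe brain-like tissue was simulated with a shifted inclusion level, "
    "so it shows the largest deviation from the cross-tissue median."
)

frac = {t: moderate_fraction(psi[t].to_numpy()) for t in psi.columns}
print("\nFraction of events with moderate PSI (0.3 < PSI < 0.75) per tissue:")
for tissue, f in sorted(frac.items(), key=lambda kv: -kv[1]):
    print(f"  {tissue:<10} {f:.2f}")
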