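"""Knockdown dPSI groups versus upstream binding (Steel-Dwass all-pairs).

Simulates a repressor knockdown: bound events gain inclusion (dPSI >= 0.2,
"UP"), a few indirect targets lose it ("DOWN"), the rest stay "NEUTRAL".
Upstream coverage of the three groups is then compared with the Steel-Dwass
test; the repressor signature is UP >> NEUTRAL ~ DOWN.
"""

import numpy as np

from exon5uc.coverage import build_coverage_matrix, stratified_upstream_coverage
from exon5uc.models import CodingType, SpliceClass
from exon5uc.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_coverage,
    simulate_knockdown,
)
from exon5uc.splicing import delta_psi_condition, generate_se_events, psi_from_tpm

quotas = {(ct, sc): 0 for ct in CodingType for sc in SpliceClass}
quotas[(CodingType.TYPE2_5UC, SpliceClass.ASE)] = 150
cfg = SimulationConfig(seed=19, quotas=quotas, psi_uniform=(0.2, 0.6), kd_down_fraction=0.25)

dataset = simulate_annotation(cfg)
events = generate_se_events(dataset.genes)
ctrl_tpm, kd_tpm, _ = simulate_knockdown(dataset)

groups = {}
for ev in events:
    p_ctrl = psi_from_tpm(ev, ctrl_tpm)
    p_kd = psi_from_tpm(ev, kd_tpm)
    if np.isfinite(p_ctrl) and np.isfinite(p_kd):
        groups[ev.skipped_exon] = delta_psi_condition(p_kd, p_ctrl)[1]

sizes = {g: list(groups.values()).count(g) for g in ("UP", "NEUTRAL", "DOWN")}
print("dPSI group sizes:", sizes)

track, _ = simulate_coverage(dataset)
matrix = build_coverage_matrix(track, list(groups))
result, box = stratified_upstream_coverage(matrix, groups)

print("\nSteel-Dwass all-pairs comparison of upstream coverage:")
print(result.table.to_string(index=False))
print(
    "\nUP events (released by the knockdown) carry significantly more "
    "upstream binding than either other group; NEUTRAL vs DOWN is flat — "
    "the expected signature of a repressor bound to the upstream intron."
)
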