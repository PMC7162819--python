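"""Infer putative virus–host links from horizontal gene transfer.

Plants transfer events between viral lineages and host groups, mixes in
gate-failing background hits, detects HGT candidates by dual-database
best-hit comparison and builds the weighted virus–host network.
"""

from gvmags.hgt import build_network, detect_hgt, host_fraction_summary
from gvmags.synth import generate_hgt_scenario

records, truth = generate_hgt_scenario(
    n_lineages=3, n_hosts=3,
    planted_edges=[("L1", "H1", 6), ("L2", "H2", 3), ("L2", "H3", 1)],
    background_hits=60, seed=4,
)
candidates = detect_hgt(records)
print(f"hit records examined : {len(records)}")
print(f"HGT candidates found : {len(candidates)} (planted: {len(truth.labels)})")

network = build_network(candidates, min_weight=2)
for u, v, data in sorted(network.edges(data=True)):
    print(f"  edge {u} -- {v}: {data['weight']} transfers")

summary = host_fraction_summary(
    candidates, {"H1": "Opisthokonta", "H2": "SAR", "H3": "Amoebozoa"}
)
print("host supergroup proportions:", {k: round(v, 2) for k, v in summary.items()})
# Each candidate is a viral protein whose best cellular hit (E <= 1e-50,
# identity and alignment fraction >= 50 %) beats its best cross-lineage
# viral hit. The L2--H3 link (1 transfer) falls below the min_weight=2
# network filter.
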