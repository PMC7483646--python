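"""Stability assessment: ddG aggregation, hotspots, and salt-bridge loss.

A synthetic saturation scan (19 substitutions x 15 sites, 5 runs x 20
frames) is aggregated into mean ddG per cell; sites where most substitutions
are destabilizing (mean ddG >= 3 kcal/mol) are structural hotspots.  The
curated salt-bridge table of the ULK1 kinase domain then drives the
charge-compatibility rule for bridge-abolishing mutations.
"""

import mutassess as ma
from mutassess import datasets, synthetic as syn

records = syn.make_ddg_scan(15, hotspot_sites=[3, 8, 11], effect=8.0, noise=0.3,
                            runs=5, frames=20, seed=4)
scan = ma.aggregate_scan(records)
hotspots = ma.find_hotspots(scan, site_fraction=0.5, damaging_threshold=3.0)
print(f"planted hotspot sites 3, 8, 11 -> recovered: {sorted(p for p, _ in hotspots)}")

pos, wt = hotspots[0]
sub = next(c for c in "ACDEFGHIKLMNPQRSTVWY" if c != wt)
category = ma.classify_stability(scan, pos, wt, sub)
print(f"example cell {wt}{pos}{sub}: mean ddG {scan.cell(pos, wt, sub):.2f} kcal/mol -> {category}")

print("\nsalt-bridge loss rule on the curated kinase-domain bridges:")
bridges = datasets.ulk1_salt_bridge_records("charmm22star")
for pos, wt, sub in [(152, "R", "L"), (138, "D", "N"), (113, "D", "E"), (268, "D", "H")]:
    flag, hits = ma.saltbridge_loss(
        datasets.ulk1_salt_bridge_records("charmm27" if pos == 152 else "charmm22star"),
        pos, wt, sub,
    )
    partners = ", ".join(f"{b.residue_a.label}-{b.residue_b.label} ({b.persistence:.1f}%)" for b in hits)
    print(f"  {wt}{pos}{sub}: loss={flag}  bridges: {partners or 'none'}")
print("\nOnly charge-destroying substitutions at bridged sites (R152L, D268H) are")
print("called damaging; D->E swaps and D->N against basic partners are retained.")
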