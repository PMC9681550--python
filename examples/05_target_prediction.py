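"""Predict tsRNA binding sites in 3'UTRs by seed match plus duplex score.

Plants perfect reverse-complement sites for one fragment into 5 of 30
random UTRs, scans every UTR for seed matches (fragment positions 2-8),
scores the full gapless duplex (G:C=+3, A:T=+2, G:T=+1, mismatch=-1), and
ranks targets by their best site.
"""

from tsrnakit import simulate as sim
from tsrnakit import targets as tgt

frag = "GATCGCGATATACCGTAA"  # 18-mer, 8 G/C + 10 A/T: perfect score 44
utrs, truth = sim.simulate_utrs({"tsRNA-x": frag}, n_targets=30,
                                planted_sites=5, seed=14)

edges = tgt.rank_targets({"tsRNA-x": frag}, utrs, top_n=10)
print("top predicted targets (score 44 = perfect duplex):")
print(edges.drop(columns="pairing").to_string(index=False))

planted = set(truth["target_id"])
print(f"\nplanted targets: {sorted(planted)}")
print(f"recovered in top edges: {sorted(set(edges['target_id']) & planted)}")

best = tgt.scan_utr(frag, utrs[truth['target_id'].iloc[0]])[0]
print(f"\npairing diagram at the best site ('|' Watson-Crick, ':' wobble):")
print(f"  UTR[{best.site_start},{best.site_end}]  {best.pairing}  "
      f"score {best.score}")
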