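"""Classify tsRNA fragments against a tRNA reference.

Builds a small synthetic genome with tRNA genes, cuts 60 fragments from the
canonical tRF regions, re-maps them, and prints the class of each of the
first few together with the catalog-wide type proportions.  tRF-5/tRF-3 are
anchored at the mature 5'/3' ends, i-tRF is internal, tRF-1 comes from the
precursor's 3' trailer and 5'U-tRF from its 5' leader.
"""

from tsrnakit import catalog as cat
from tsrnakit import simulate as sim

genes, genome, _ = sim.simulate_trna_genes(n_genes=15, seed=1)
models = cat.build_reference_models(genes, genome)
records, truth = sim.simulate_catalog(models, n_fragments=60, seed=2)
cat.classify_catalog(records, models)

print("fragment_id       type      loop            parents")
for rec in records[:8]:
    parent = rec.parents[0]
    print(f"{rec.fragment_id}   {rec.type:8s}  {rec.cleavage_loop:14s}"
          f"  {parent.gene_id}:{parent.context}[{parent.start},{parent.end}]")

summary = cat.summarize_catalog(records)
print("\ntype proportions (fraction of catalog):")
print(summary["by_type"].round(3).to_string())
print("\nA tRF-5 labelled 'D-loop' was cleaved inside the D-loop; the")
print("proportions recover the mixture the generator planted.")
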