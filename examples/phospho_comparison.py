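"""Compare condition-specific phosphosite sets and count kinase enrichment.

Uses the deterministic fixtures that mirror published comparison patterns:
a MAP1B site set with a single site shared between two stressors, and an
82-site set of which 4 are shared.  Also runs a small hypergeometric
enrichment against a toy kinase-substrate map.
"""

from axonmt import synth
from axonmt.phospho import (
    compare_conditions,
    count_sites_per_protein,
    enrich_terms,
    filter_significant,
)

table_a, table_b, _ = synth.phospho_fixture("map1b")
up_a, _ = filter_significant(table_a)
up_b, _ = filter_significant(table_b)
overlap = compare_conditions(up_a, up_b)
print(f"MAP1B sites: {overlap.n_a} (peroxide) vs {overlap.n_b} (arsenite), "
      f"shared {overlap.n_shared}: {sorted(overlap.intersection)}")

table_a, table_b, _ = synth.phospho_fixture("arsenite82")
up_a, _ = filter_significant(table_a)
up_b, _ = filter_significant(table_b)
overlap = compare_conditions(up_a, up_b)
print(f"site sets: {overlap.n_shared} of {overlap.n_b} arsenite sites shared "
      f"({100 * overlap.fraction_of_b_shared:.1f} % < 5 %)")

counts = count_sites_per_protein(up_a)
print("\ntop proteins by upregulated site count (peroxide set):")
print(counts.head(3).to_string(index=False))

background = sorted(up_a.genes | up_b.genes | {f"GENE{i:04d}" for i in range(50)})
terms = {
    "kinase_map_binding": {g for g in background if g.startswith("MAP")},
    "kinase_generic": set(background[:20]),
}
results = enrich_terms(up_a.genes, terms, background)
print("\nkinase-substrate enrichment (hypergeometric, BH-adjusted):")
for r in results:
    print(f"  {r.term}: overlap {r.overlap}/{r.term_size}, p = {r.p_value:.2e}, "
          f"adjusted p = {r.p_adjusted:.2e}")
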