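"""TSS calling from 5' sequence tags and expression-based gene classes.

5'-end tags are grouped by exact genomic position and strand into a TSS
table; each gene gets the highest-count TSS near its coding span as its
primary TSS. Expression tables (two conditions, two technical replicates)
yield activity ranks (top/bottom n by treated intensity) and fold-change
classes (>= 2-fold up or down, inclusive; 'constant' = smallest |log2 FC|
among well-expressed genes).
"""

import monodi as m

model = m.make_genome(2, 200_000, 40, seed=5,
                      class_counts={"constant": 13, "up": 8, "down": 13})

# --- TSS calling ---------------------------------------------------------
tags = m.simulate_tss_tags(model, 100_000, seed=6)
tss = m.call_tss(tags)
print(f"{len(tss)} distinct TSS positions from {tags.total} tags")
print("tag-count tiers:", tss.tier_counts((100, 1000)), "(strict > thresholds)")

genes = [m.Gene(g.gene_id, g.chrom, g.cds_start, g.cds_end, g.strand)
         for g in model.genes]
genes = m.assign_primary_tss(genes, tss)
truth = {g.gene_id: g.tss for g in model.genes}
hits = sum(g.tss == truth[g.id] for g in genes)
print(f"primary TSS equals the generator's true TSS for {hits}/{len(genes)} genes")

# --- expression classes --------------------------------------------------
expr = m.simulate_expression(model, seed=7)
regulation = m.fold_change_classes(expr, fc_threshold=2.0, n_constant=13)
activity = m.classify_activity(expr, genes, n=10)
sizes = {c: sum(v == c for v in regulation.values())
         for c in ("up", "down", "constant")}
print("fold-change classes (designed 8 up / 13 down / 13 constant):", sizes)
print("active genes:", sorted(g for g, v in activity.items() if v == "active")[:5], "...")
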