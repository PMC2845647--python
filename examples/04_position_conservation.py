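"""Conservation of mononucleosome positions between TSA-treated and untreated
conditions, as squared Pearson correlation of coverage profiles.

The generator repositions body nucleosomes of regulated (up/down) genes under
TSA while promoters stay put, so regulated gene bodies should show low r^2
and promoters high r^2; constant genes should show no systematic
body-vs-promoter difference (paired Wilcoxon signed-rank).
"""

import numpy as np

import monodi as m
from monodi.experiments import conservation_contrast

rows, classes = conservation_contrast(n_fragments=120_000, seed=9)

print("median r^2 by (class, region):")
table = m.median_by_class(rows, classes)
print(table.to_string(index=False))

print("\npaired body-vs-promoter signed-rank per class:")
for cls in ("constant", "down", "up"):
    sub = [r for r in rows if classes.get(r.gene_id) == cls]
    res = m.body_promoter_test(sub)
    print(f"  {cls:9s} n={res.n_used:3d}  W={res.w:7.1f}  p={res.p:.3g} ({res.method})")

reg = {g for g, c in classes.items() if c in ("up", "down")}
body = np.median([r.r2 for r in rows if r.gene_id in reg and r.label == "body"])
prom = np.median([r.r2 for r in rows if r.gene_id in reg and r.label == "promoter"])
print(f"\nregulated genes: median body r^2 {body:.2f} < promoter r^2 {prom:.2f} —")
print("repositioning hits the nucleosome-dense bodies, promoters stay conserved.")
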