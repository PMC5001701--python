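"""Narrow the analyzed miRNA set with the two biological filters.

Keeps miRNAs that are (a) expressed in the relevant tissues/cell types or
(b) intragenic to a gene (or extension TF) of the studied pathways — the
union of the two criteria, each retained miRNA annotated with why it was
kept.
"""

from mirpath import (
    candidate_set,
    expression_filter,
    extend_with_tfs,
    intragenic_filter,
)
from mirpath.synthetic import SyntheticScenario, simulate

dataset = simulate(SyntheticScenario(seed=5))
pathways = extend_with_tfs(dataset.pathways, dataset.tf_edges)
names = sorted(dataset.vmt.targets)

expressed = expression_filter(names, dataset.expression)
intragenic = intragenic_filter(names, pathways, dataset.hosts)
candidates = candidate_set(expressed, intragenic, mode="union")

print(f"{len(names)} miRNAs in; {len(expressed)} pass the tissue-expression "
      f"criterion, {len(intragenic)} the intragenic-host criterion")
print(f"union -> {len(candidates)} candidates enter the enrichment analysis")
both = [m for m, why in candidates.items() if len(why) == 2]
print(f"{len(both)} satisfy both criteria, e.g.:")
for m in both[:3]:
    print(f"  {m}: tissues={sorted(expressed[m])}, "
          f"hosts={sorted(intragenic[m])}")
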