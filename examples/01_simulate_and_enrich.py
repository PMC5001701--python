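"""Simulate a study with planted miRNAs and run the full enrichment.

Generates a synthetic study — 39 relevance-classed pathways, 500 miRNAs,
10 of which are planted with 5x target enrichment in three class-A
pathways each — then runs contingency construction, one-tailed Fisher
tests, BH correction and the weighted Lancaster combination under the
moment-matched null, and reports how the planted miRNAs ranked.
"""

from mirpath import (
    enrichment_analysis,
    extend_with_tfs,
    truth_recovery_report,
)
from mirpath.synthetic import planted_scenario, simulate

scenario = planted_scenario(seed=0)  # defaults: 10 planted, odds 5
dataset = simulate(scenario)
pathways = extend_with_tfs(dataset.pathways, dataset.tf_edges)

result = enrichment_analysis(pathways, dataset.vmt, seed=0)

print(f"scored {len(result.scores)} miRNAs over "
      f"{len(result.pathway_ids)} pathways "
      f"(null: {result.null.kind}, effective df "
      f"{result.null.df_effective:.2f} of nominal "
      f"{result.scores[0].df_nominal:.1f})")
print(f"{len(result.selected)} miRNAs selected at p < 0.01\n")

print("top 5 by combined p-value (-log10 p is the plotted score):")
for s in result.scores[:5]:
    print(f"  {s.rank:>3}  {s.mirna}  T={s.lancaster_T:7.2f}  "
          f"p={s.p_combined:.3g}  -log10(p)={s.neg_log_p:.2f}")

report = truth_recovery_report(dataset.truth, result.scores)
print(f"\nplanted-miRNA recovery: {report.top_decile_fraction:.0%} of the "
      "10 planted miRNAs rank in the top decile")
print("(ranks: "
      + ", ".join(str(int(r)) for _, r, _ in report.per_mirna) + ")")
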