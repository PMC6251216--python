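"""Dual screening of interval variants: diversity panel + recessive bulk.

A causal recessive allele must be absent from every normal-phenotype
accession of a diversity panel and (near-)fixed in pooled reads of
recessive-phenotype segregants. The intersection of both screens, placed
against gene models, nominates the candidate gene.
"""

from bsamap.fixtures import make_funnel_fixture
from bsamap.screen import run_screen

funnel = make_funnel_fixture(seed=7)
report = run_screen(
    funnel["variants"], funnel["panel"], funnel["pool"], funnel["genes"],
    min_depth=10, min_alt_fraction=0.95,
    p_values=funnel["p_values"],
)

counts = report.funnel()
print(f"interval variants       : {counts['input']}")
print(f"panel screen retained   : {counts['panel_retained']}  (no carrier among 822 accessions)")
print(f"pool screen retained    : {counts['pool_retained']}  (alt fraction >= 0.95 at depth >= 10)")
print(f"intersection            : {counts['intersection']}")
print(f"nominated gene          : {report.nominated_gene}\n")
print(report.to_frame().to_string(index=False))
print(
    "\nFive of the six shared candidates fall in or next to one gene;"
    "\nthe sixth is intergenic. The panel screen is the sharper filter"
    f"\n({counts['input'] - counts['panel_retained']} of {counts['input']}"
    " variants removed) but both agree on the final six."
)
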