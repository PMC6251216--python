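"""Consequence of a splice-donor-destroying deletion.

A 20-nt stretch spanning the end of exon 2 and the GT donor of intron 2 is
replaced by 6 nt. Without its donor the intron is retained in the mature
transcript, intronic sequence enters the reading frame, and translation
terminates early inside the MYB DNA-binding domain.
"""

from bsamap import AlternativeSpliceSite, alternative_splice_isoforms, characterize
from bsamap.fixtures import KAN1_DOMAINS, KAN1_EVENT, make_kan1_like_gene

gene = make_kan1_like_gene()
print(f"gene {gene.gene_id}: {gene.length} bp, {len(gene.exons)} exons")
print(f"event: replace gene positions {KAN1_EVENT.start}-{KAN1_EVENT.end} "
      f"({gene.sequence[KAN1_EVENT.start - 1:KAN1_EVENT.end]}) "
      f"with {KAN1_EVENT.replacement}\n")

rep = characterize(gene, KAN1_EVENT, KAN1_DOMAINS)
print(f"wild protein          : {rep.wild_protein_length_aa} aa")
print(f"retained introns      : {rep.retained_introns}")
print(f"frameshift            : ORF position {rep.frameshift_cdna_pos}")
print(f"first altered residue : {rep.first_altered_residue} "
      f"({rep.wild_run} -> {rep.mutant_run})")
print(f"premature stop        : {rep.premature_stop_codon} at residue "
      f"{rep.premature_stop_residue}")
print(f"mutant protein        : {rep.mutant_protein_length_aa} aa "
      f"(ORF {rep.mutant_orf_length_nt} nt), {rep.classification}")
for d in rep.domain_overlaps:
    print(f"domain {d.name} ({d.start}-{d.end}) : {d.status}")

# a 3-nt alternative acceptor produces a second isoform one residue shorter
iso = alternative_splice_isoforms(gene, AlternativeSpliceSite(4, 3, end="acceptor"))
print(f"\nalternative acceptor at intron 4 (+3 nt):")
for report in iso:
    print(f"  {report.name}: {len(report.translation.protein)} aa"
          + (" (frameshifted)" if report.frameshifted else ""))
print(
    "\nThe truncation removes the C-terminal half of the MYB domain: the"
    "\nnew terminator lands inside it, so DNA binding is expected lost."
)
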