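"""Codon usage and RSCU of simulated protein-coding genes.

Simulates a small family, takes one genome's 13 PCGs, extracts codons under
the vertebrate mitochondrial code and prints the most used codons by RSCU
(relative synonymous codon usage: observed count / family mean; 1 = no
bias) plus the most abundant amino acids.
"""
from mitocompare import codon_usage_rscu, extract_codons
from mitocompare.synthetic import SimulationSpec, simulate_family

genomes, _ = simulate_family(SimulationSpec(seed=1, n_taxa=2))
g = genomes[0]
extractions = [extract_codons(g.feature_seq(f), f.name)
               for f in g.features if f.gene_class == "PCG"]
print("start/stop codons of the first five genes:")
for ex in extractions[:5]:
    print(f"  {ex.gene:<6} start {ex.start_codon}  stop {ex.stop_codon}")

table = codon_usage_rscu(extractions)
print(f"\ntotal codons counted (stops excluded): {table.total_codons}")
frame = table.to_frame().query("family != 'stop'")
top = frame.sort_values("rscu", ascending=False).head(5)
print("five codons with highest RSCU (most over-used within their family):")
print(top[["codon", "amino_acid", "count", "rscu"]].to_string(index=False))
print("most abundant amino acids:", ", ".join(table.top_amino_acids(4)))
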