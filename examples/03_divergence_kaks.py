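"""Pairwise divergence: K2P distance and Nei-Gojobori Ka/Ks.

Simulates a two-taxon family with known per-gene dN/dS, then estimates
transition/transversion proportions, the Kimura 2-parameter distance and
NG86 Ka/Ks for each gene.  Ka/Ks < 1 indicates purifying selection — the
planted regime for all mitochondrial PCGs here.
"""
from mitocompare.divergence import nei_gojobori_kaks
from mitocompare.synthetic import SimulationSpec, simulate_family

spec = SimulationSpec(seed=4, n_taxa=2, cr_repeat_taxon=None,
                      rearrangements=())
genomes, truth = simulate_family(spec)
a, b = genomes

print(f"{'gene':<6} {'planted w':>9} {'Ka':>8} {'Ks':>8} {'Ka/Ks':>7}")
for feat in a.features:
    if feat.gene_class != "PCG":
        continue
    r = nei_gojobori_kaks(a.feature_seq(feat), b.feature_seq(feat))
    w = spec.per_gene_omega[feat.name]
    ratio = f"{r.ka_ks:.4f}" if r.ka_ks is not None else "undef"
    print(f"{feat.name:<6} {w:>9.3f} {r.ka:>8.4f} {r.ks:>8.4f} {ratio:>7}")
print("\nKa/Ks well below 1 across genes = strong negative (purifying) "
      "selection, matching the planted omega values up to estimator noise.")
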