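"""Call fixed SNPs between two simulated parental strains.

Generates ~35x pileups for a maternal and a paternal strain, including
sites engineered to fail each calling criterion, then applies the rule:
>= 13 reads in each strain, major base >= 95%, consensus bases differ.
"""

from ezdc.simulate import SimConfig, simulate_annotation, simulate_strain_pileups
from ezdc.snp import CallerConfig, call_fixed_snps, genes_with_snp, residual_polymorphism

cfg = SimConfig(n_genes=500, seed=7)
pile_a, pile_b, truth = simulate_strain_pileups(cfg)
snps = call_fixed_snps(pile_a, pile_b, CallerConfig())

print(f"pileup positions: {len(pile_a)}")
print(f"fixed SNPs called: {len(snps)} (truth: {(truth['status'] == 'fixed').sum()})")
print(f"residual within-strain polymorphism, strain B: {len(residual_polymorphism(pile_b))} sites")

annot = simulate_annotation(cfg)
per_gene = genes_with_snp(snps, annot)
frac = (per_gene > 0).mean()
print(f"genes with >= 1 exonic fixed SNP: {(per_gene > 0).sum()}/{len(per_gene)} ({frac:.0%})")
print("-> these are the genes whose reads can be assigned to a parental chromosome")
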