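"""Draw a synthetic dataset with the nested pooled-replicate study design.

Two invasion categories (ancient / recent), four sites each, two pooled-RNA
replicate libraries per site: 16 libraries. A 5% fraction of genes carries a
planted invasion effect (log2 fold changes of mean magnitude 2), and each
gene has its own random site effects, the structure that makes this design
statistically hard.
"""

from consensusde import SimulationConfig, simulate_dataset

config = SimulationConfig(n_genes=2000, seed=42)
counts, design, truth = simulate_dataset(config)

print(f"count matrix: {counts.n_genes} genes x {counts.n_libraries} libraries")
print(f"sites: {design.sites}")
print(design.table[["library_id", "invasion_category", "pool_size",
                    "n_males", "n_females"]].head(4).to_string(index=False))
print(f"genes with a true invasion effect: {truth.genes['is_de'].sum()}")
print(f"genes labeled immune:             {truth.genes['is_immune'].sum()}")
de = truth.genes[truth.genes.is_de]
print(f"mean |true log2 FC| of DE genes:  {de['true_lfc'].abs().mean():.2f}")
# The planted fold changes are what the DE strategies later try to recover;
# pool sizes (6-10, balanced sex) are metadata mirroring the field sampling.
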