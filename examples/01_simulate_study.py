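"""Generate a synthetic two-group miRNA/mRNA study with planted structure.

The generator emulates a tumor-versus-normal deep-sequencing design
(17 tumors, 4 normal germinal-center-like controls by default): NB counts
for both assays, a random miRNA-target / TF-gene regulatory prior, five
up-regulated driver miRNAs whose validated targets are repressed, and 10%
independently DE genes. The printed ground truth is what the downstream
stages are expected to recover.
"""

from mirlink import SimConfig, simulate_study

cfg = SimConfig(seed=7)
edges, mirna, mrna, sheet, truth = simulate_study(cfg)

print(f"miRNA counts: {mirna.shape[0]} features x {mirna.shape[1]} samples")
print(f"mRNA  counts: {mrna.shape[0]} features x {mrna.shape[1]} samples")
print(f"regulatory prior: {len(edges)} edges "
      f"({len(edges.of_type('mirna_target'))} miRNA-target, "
      f"{len(edges.of_type('tf_gene'))} TF-gene)")
print(f"planted drivers (log2FC +{cfg.lfc_mirna}): "
      + ", ".join(truth.drivers['mirna_id']))
print(f"planted DE genes: {len(truth.de_genes)}; "
      f"planted repression pairs: {len(truth.pairs)}")
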