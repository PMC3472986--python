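"""Simulate a two-library restriction-tag (DGE) experiment.

Builds a small reference transcriptome, draws two-condition expression with
5% truly differentially expressed genes, and emits noisy 49bp raw reads the
way the NlaIII/MmeI protocol would: each transcript contributes its 3'-most
CATG+17 tag followed by the 3' adaptor.
"""

from tagdge import generate_reference, simulate_expression, simulate_reads

ref = generate_reference(n_genes=500, length_range=(200, 2000), seed=11)
truth, counts1, counts2 = simulate_expression(
    ref, de_fraction=0.05, fold_range=(4.0, 16.0), depth1=50_000, depth2=50_000, seed=11
)
reads = simulate_reads(counts1, ref, error_rate=0.01, seed=11)

n_de = int(truth.table["is_de"].sum())
print(f"reference: {len(ref)} genes, genome of {len(ref.genome):,}nt "
      f"({len(ref.intergenic)} intergenic spacers)")
print(f"expression truth: {n_de} DE genes of {len(ref)} "
      f"(folds {truth.table.loc[truth.table.is_de, 'fold_change'].min():.2f}"
      f"-{truth.table.loc[truth.table.is_de, 'fold_change'].max():.2f})")
print(f"library 1: {counts1.sum():,} tags over {int((counts1 > 0).sum())} genes")
print(f"raw reads: {len(reads):,} x 49nt; first read: {reads.reads[0]}")
classes = {}
for cls, _ in reads.provenance:
    classes[cls] = classes.get(cls, 0) + 1
print("read provenance:", ", ".join(f"{k}={v}" for k, v in sorted(classes.items())))
# 'sense' reads carry real transcript tags; antisense/intergenic/empty reads
# are the protocol artefacts the cleaning and mapping stages must absorb.
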