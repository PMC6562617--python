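"""Summarize retinal per-exon read counts and call gene expression.

Per-exon read counts are generated for a set of retina genes (positive
controls known to be retina-expressed, negative controls known not to be,
and the candidate). Each gene gets a total and a mean-reads-per-exon
summary; the candidate is called EXPRESSED when its mean exceeds twice the
strongest negative control.
"""

from pedscout import expression_call, gene_span_kb, summarize_gene
from pedscout.datasets import (
    NECAP1_GENE,
    RETINA_EXPRESSED_CONTROLS,
    RETINA_NON_EXPRESSED_CONTROLS,
    RETINA_EXON_SUMMARY,
)
from pedscout.cli import _default_exon_specs
from pedscout.expression import read_exon_table
from pedscout.simulate import gen_exon_counts

import tempfile
from pathlib import Path

counts = gen_exon_counts(_default_exon_specs(), seed=7)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "exon_counts.tsv"
    counts.to_csv(path, sep="\t", index=False)
    genes = read_exon_table(path)

summaries = {g.gene: summarize_gene(g) for g in genes}
print(f"{'gene':<10} {'exons':>5} {'total':>7} {'mean/exon':>9}")
for gene, s in sorted(summaries.items()):
    print(f"{gene:<10} {s.n_exons:>5} {s.total_reads:>7} {s.mean_reads_per_exon:>9}")

call = expression_call(
    summaries["NECAP1"],
    [summaries[g].mean_raw for g in RETINA_EXPRESSED_CONTROLS],
    [summaries[g].mean_raw for g in RETINA_NON_EXPRESSED_CONTROLS],
)
span = gene_span_kb(NECAP1_GENE.start, NECAP1_GENE.end)
print(f"\nNECAP1: {call}, gene span {span} kb")
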