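"""Genome statistics from an annotated record.

Builds a small annotated genome in memory (the same information a GenBank
flat file carries) and computes the classic genome-table rows: size, G+C
content, coding base pairs as the merged union of CDS segments, and gene
counts.
"""

import numpy as np

from diffpick import AnnotatedRecord, Feature, genome_stats

rng = np.random.default_rng(4)
seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
features = [
    Feature("CDS", "+", [(101, 1300)], {"product": "hypothetical protein"}),
    Feature("CDS", "-", [(1200, 2400)], {}),          # overlaps the first CDS
    Feature("CDS", "+", [(3000, 3500), (3600, 4100)], {}),  # join() segments
    Feature("tRNA", "+", [(5000, 5075)], {}),
    Feature("rRNA", "-", [(6000, 7500)], {}),
    Feature("CDS", "+", [(8000, 8400)], {}, pseudo=True),
]
record = AnnotatedRecord("demo", len(seq), seq, features)

st = genome_stats(record)
print(f"Genome size (bp)      {st.size:>10,}")
print(f"DNA G+C (bp)          {st.gc_bp:>10,}   {st.gc_pct:.2f} %")
print(f"DNA coding (bp)       {st.coding_bp:>10,}   {st.coding_pct:.2f} %  (CDS union, overlaps merged)")
print(f"Total genes           {st.n_total_genes:>10}")
print(f"Protein coding genes  {st.n_cds:>10}")
print(f"RNA genes             {st.n_rna:>10}")
print(f"Pseudo genes          {st.n_pseudo:>10}")
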