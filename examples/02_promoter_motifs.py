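"""Scan promoters for the TATA box and the Msn2/4 stress-response element.

Extracts strand-aware TSS-relative [-400, +100] promoter windows from a
synthetic genome with planted class-specific motif frequencies, runs the
directed consensus search (TATAWAW within [-200, 0]; (A/C/G)AGGGG within
[-300, -50]) and tabulates motif content per gene class.
"""

from nascentclass.annotation import analyzed_genes
from nascentclass.motifs import class_motif_table, extract_promoters, scan_all
from nascentclass.simulate import GeneratorParams, simulate

ds = simulate(GeneratorParams(n_genes=1500, seed=0), components=("promoters",))
ana = ds.gene_table.loc[analyzed_genes(ds.gene_table)]
windows = extract_promoters(ds.genome, ana)
print(f"promoter windows extracted: {len(windows)} (501 bp each)")

calls = scan_all(windows)
table = class_motif_table(calls, ds.truth.loc[ana.index, "true_class"])
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

# Coactivator-redundant promoters carry TATA at ~65% and the Msn2/4 site at
# ~26%, versus ~25% and ~14% for TFIID-dependent promoters; the Fisher
# p-values quantify the class enrichment of each motif.
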