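"""Map factor binding from ChEC-seq cleavage tracks.

Normalizes MNase-fusion cleavage tracks to spike-in totals, calls peaks
against a free-MNase control (2-fold over control and local background,
0.1% FDR), assigns peak summits to promoters ([-300, +100] of the TSS),
forms the 3-of-4 replicate consensus and reports the co-binding overlap
between the two factors.
"""

from nascentclass import chec
from nascentclass.annotation import analyzed_genes
from nascentclass.simulate import GeneratorParams, simulate

ds = simulate(GeneratorParams(n_genes=200, n_chroms=2, seed=3), components=("chec",))
ana = ds.gene_table.loc[analyzed_genes(ds.gene_table)]
control = chec.normalize_chec(ds.chec_control)

tables = {}
for factor, replicates in ds.chec_tracks.items():
    assignments, tracks = [], []
    for raw in replicates:
        track = chec.normalize_chec(raw)
        peaks = chec.call_peaks(track, control)
        assignments.append(chec.assign_peaks_to_promoters(peaks, ana))
        tracks.append(track)
    table = chec.replicate_consensus(assignments, ana, tracks)
    tables[factor] = table
    bound = ds.truth.loc[ana.index, f"bound_{factor}"]
    called = table["consensus_bound"]
    print(
        f"{factor}: {int(called.sum())} consensus-bound promoters "
        f"(recall {called[bound].mean():.1%}, "
        f"false calls {called[~bound].mean():.1%})"
    )

overlap = chec.factor_overlap(tables)
row = overlap.iloc[0]
print(
    f"co-binding: {row['n_intersection']} promoters bound by both factors "
    f"({row['fraction_of_smaller']:.1%} of the smaller set)"
)

# With 8-fold planted enrichment and four replicates the consensus rule
# recovers essentially all planted sites with no false promoters, and the
# planted ~90% co-binding of the two factors is reproduced.
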