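"""Group discovered motifs by shift-tolerant sequence similarity."""

from seedfold.motif_clustering import cluster_motifs, motif_distance

motifs = [
    "UGUAUAUAU", "GUAUAUAUG", "UUGUAUAUA",   # shifted copies of one signal
    "UGUGUGUGU", "GUGUGUGUG",                 # a UG-run family
    "GGCGGCGGC",                              # unrelated, GC-rich
]
print("d(UGUAUAUAU, GUAUAUAUG) =", motif_distance("UGUAUAUAU", "GUAUAUAUG"))

for c in cluster_motifs(motifs, diameter=3.0):
    print(f"cluster members={c.members} mean_gc={c.mean_gc:.3f}")
# The distance is the minimal shift + mismatches over both alignments, so
# one-base-shifted copies sit at distance 1 and fall into one cluster; the
# average GC content separates AU-rich (Pumilio-like) clusters from GC-rich
# ones.
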