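"""Predict canonical seed-match sites in a 3'-UTR and cut target windows."""

from seedfold import (
    MirnaFamily, UTRRecord, extract_window, find_seed_sites,
    maximal_independent_set,
)
from seedfold.io import reverse_complement

family = MirnaFamily("mir-demo", "GAGGUAG")   # seed = miRNA positions 2-8
site = reverse_complement(family.seed)         # what the UTR must carry

# a 600-nt UTR with three planted sites, two of them 30 nt apart
seq = list("A" * 600)
for pos in (100, 130, 400):
    seq[pos : pos + 7] = site
utr = UTRRecord("DEMO1", "".join(seq))

sites = find_seed_sites(utr, family)
print(f"{len(sites)} seed-match sites:")
for s in sites:
    print(f"  {s.gene_id}:{s.start}-{s.end}  {s.site_type}")

windows = [w for s in sites if (w := extract_window(utr, s)) is not None]
kept = maximal_independent_set(windows)
print(f"{len(windows)} windows extracted, {len(kept)} kept after overlap thinning")
print("kept window starts:", [w.utr_start for w in kept])
# The two sites 30 nt apart conflict (starts closer than 100 nt), so the
# maximum independent set keeps one of them plus the distant site.
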