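"""Score window accessibility (dG_open, GA) and rank least-accessible first."""

from seedfold.accessibility import rank_windows
from seedfold.synthetic import SyntheticSpec, generate_windows

spec = SyntheticSpec(n_windows=30, seed=7)
windows, truth = generate_windows(spec)
ranked, _ = rank_windows(windows)

print("rank  window  dG_all  dG_masked  dG_open      GA  structured")
structured = dict(zip(truth.window_id, truth.structured))
for rank, (w, s) in enumerate(ranked, start=1):
    if rank <= 5 or rank > len(ranked) - 3:
        print(
            f"{rank:4d}  {w.window_id}  {s.dg_all:6.1f}  {s.dg_masked:9.1f}"
            f"  {s.dg_open:7.1f}  {s.ga:6.1f}  {structured[w.window_id]}"
        )
# GA = 2*dG_all - dG_masked (pseudo-kcal/mol, internal engine): the more
# negative, the more energy opening the site costs.  Windows with a planted
# stem over the seed site (structured=True) head the list.
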