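"""MaxChi recombination screen on a constructed recombinant.

Two diverged parents and a recombinant that switches template at the 21st
polymorphic site; MaxChi scans every breakpoint of each pair's
match/mismatch vector and reports the permutation probability of the maximal
chi-square.
"""

import numpy as np

from hapsel import alignment_from_strings, maxchi
from hapsel.simulate import _random_coding_sequence

rng = np.random.default_rng(0)
p1 = _random_coding_sequence(200, rng)
pos = np.sort(rng.choice(600, size=40, replace=False))
p2 = list(p1)
for i in pos:
    p2[i] = [b for b in "ACGT" if b != p1[i]][int(rng.integers(3))]
p2 = "".join(p2)
recombinant = p1[: int(pos[20])] + p2[int(pos[20]) :]

aln = alignment_from_strings({"parent1": p1, "parent2": p2, "rec": recombinant})
for r in maxchi(aln, n_perm=1000, seed=1):
    flag = "RECOMBINATION" if r.significant else "ok"
    print(
        f"{r.pair[0]:8s} x {r.pair[1]:8s}  breakpoint after polymorphic site "
        f"{r.best_breakpoint_index} (nt {r.best_breakpoint_site})  "
        f"chi2 = {r.chi2_max:.1f}  p = {r.p:.4g}  [{flag}]"
    )
print("\nThe junction was placed after polymorphic site 20; both recombinant pairs"
      "\nshould localize it there with p < 0.01, while parent pairs stay quiet.")
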