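"""Physicochemical selection scan along a phylogeny.

Part 1 evolves a 180-codon gene along a small tree under a conservative
codon process, reconstructs ancestral sequences by Fitch parsimony and runs
the category z-test per property: drawn from the neutral enumeration, no
property should flag destabilizing selection.

Part 2 adds a constructed destabilizing hotspot - replacements drawn from
the radical (category 3) tail of the Grantham polarity index, confined to
codons 90-99 - and shows the 20-codon sliding window localizing it.
"""

import numpy as np

from hapsel import simulate_divergence
from hapsel.physchem import (
    PropertyTable,
    ReplacementEvent,
    codon_composition,
    enumerate_replacements,
    fitch_ancestral,
    load_tree,
    mm01_test,
    possible_nonsyn_changes,
    results_table,
    sliding_window,
)

L = 180
tree_s = "((A:0.6,B:0.6):0.3,(C:0.6,D:0.6):0.3);"
aln, _, _ = simulate_divergence(tree_s, L, kappa=2.0, omega=0.3, seed=11)

props = PropertyTable.bundled()
tree = load_tree(tree_s)
states = fitch_ancestral(aln, tree)
events = enumerate_replacements(states, tree, props)
comp = codon_composition(states)
print(f"{len(events)} amino-acid replacements inferred on the tree")

results = mm01_test(events, props, comp)
tab = results_table(results)
print(tab[["accession", "gof_chi2", "z_cat1", "z_cat3"]].round(2).to_string(index=False))
flagged = [r.accession for r in results if r.verdicts[-1] == "positive_destabilizing"]
print("positive-destabilizing properties:", flagged or "none at Bonferroni 5% (as expected)")

# ---- constructed destabilizing hotspot ----
acc = "GRAR740102"
rng = np.random.default_rng(3)
radical = [
    ch
    for codon, mult in comp.items()
    for ch in possible_nonsyn_changes(codon)
    if props.category(acc, *ch) == props.k
]
hot = []
for _ in range(35):
    aa_a, aa_b = radical[int(rng.integers(len(radical)))]
    ev = ReplacementEvent(("sim", "sim"), int(rng.integers(90, 100)), aa_a, aa_b)
    for a in props.accessions:
        ev.magnitudes[a] = props.magnitude(a, aa_a, aa_b)
        ev.categories[a] = props.category(a, aa_a, aa_b)
    hot.append(ev)

scan = sliding_window(events + hot, props, [acc], L, comp)
windows = scan.starts[scan.flagged[acc]]
print(f"\nhotspot scan ({acc}): windows above z = {scan.threshold:.2f} "
      f"start at codons {windows.tolist()}")
print("  (the simulated radical cluster sits in codons 90-99; flagged 20-codon"
      "\n   windows overlapping it localize the destabilizing signal)")
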