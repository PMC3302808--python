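"""Coalescent and codon-process simulators: determinism, truth consistency,
and recovery of their own generating parameters."""

import numpy as np
import pytest

from hapsel.netsel import templeton_fisher
from hapsel.seqdata import alignment_from_strings
from hapsel.simulate import (
    DivergenceEvent,
    PopSimConfig,
    simulate_divergence,
    simulate_population,
)


def test_same_seed_bit_identical():
    cfg = PopSimConfig(n=12, L_codons=150, theta=6, tip_bias=2.0, seed=77)
    a1, t1 = simulate_population(cfg)
    a2, t2 = simulate_population(cfg)
    assert [r.seq for r in a1.sequences] == [r.seq for r in a2.sequences]
    assert t1.newick == t2.newick
    assert [m.site for m in t1.mutations] == [m.site for m in t2.mutations]


def test_truth_replay_consistency():
    # infinite sites: a leaf differs from the ancestral sequence exactly at
    # the sites of the mutations on its root path, and each mutation appears
    # in exactly n_descendants leaves
    aln, truth = simulate_population(PopSimConfig(n=15, L_codons=200, theta=10, seed=5))
    anc = truth.ancestral_seq
    for m in truth.mutations:
        carriers = sum(1 for r in aln.sequences if r.seq[m.site - 1] != anc[m.site - 1])
        assert carriers == m.n_descendants
    # every difference from the ancestor is explained by some mutation
    mut_sites = {m.site for m in truth.mutations}
    for r in aln.sequences:
        diffs = {i + 1 for i, (x, y) in enumerate(zip(r.seq, anc)) if x != y}
        assert diffs <= mut_sites


def test_truth_class_labels_match_sequences():
    from hapsel.codons import classify_substitution

    _, truth = simulate_population(PopSimConfig(n=10, L_codons=150, theta=8, seed=6))
    for m in truth.mutations:
        assert classify_substitution(m.codon_from, m.codon_to).value == m.cls


def test_expected_segregating_sites_neutral():
    theta, n, reps = 5.0, 12, 400
    a1 = sum(1.0 / i for i in range(1, n))
    Ss = []
    for i in range(reps):
        _, truth = simulate_population(
            PopSimConfig(n=n, L_codons=300, theta=theta, seed=8000 + i)
        )
        Ss.append(truth.S)
    se = np.std(Ss, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(Ss) - theta * a1) <= 3 * se


def test_small_L_raises_when_sites_exhausted():
    with pytest.raises(ValueError, match="L_codons"):
        # theta huge relative to sequence length
        simulate_population(PopSimConfig(n=20, L_codons=4, theta=80, seed=1))


def test_tip_bias_direction_recovered():
    up = down = 0
    for i in range(40):
        _, t5 = simulate_population(
            PopSimConfig(n=40, L_codons=400, theta=25, tip_bias=5.0, seed=900 + i)
        )
        _, t02 = simulate_population(
            PopSimConfig(n=40, L_codons=400, theta=25, tip_bias=0.2, seed=990 + i)
        )

        def odds(t):
            tab = t.tip_interior_table().astype(float) + 0.5
            return (tab[0, 1] / tab[0, 0]) / (tab[1, 1] / tab[1, 0])

        up += odds(t5) > 1
        down += odds(t02) < 1
    assert up >= 38 and down >= 38  # >= 95% direction recovery


def test_divergence_omega_zero_all_synonymous():
    _, events, _ = simulate_divergence("(A:1.0,B:1.0);", 60, omega=0.0, seed=2)
    assert events and all(e.cls == "synonymous" for e in events)


def test_divergence_kappa_monotonicity():
    ratios = []
    for kappa in (0.5, 2.0, 8.0):
        _, events, _ = simulate_divergence(
            "(A:2.0,B:2.0);", 400, kappa=kappa, omega=0.5, seed=13
        )
        ts = sum(1 for e in events if e.is_transition)
        tv = len(events) - ts
        ratios.append(ts / max(tv, 1))
    assert ratios[0] < ratios[1] < ratios[2]


def test_divergence_zero_length_tree_no_events():
    aln, events, _ = simulate_divergence("(A:0.0,B:0.0);", 30, seed=4)
    assert events == []
    assert aln.sequences[0].seq == aln.sequences[1].seq == aln.outgroup[1]


def test_saturation_plateau_on_long_branches():
    from hapsel.popgen import saturation_scan

    rows = {}
    for blen in (0.3, 6.0):
        aln, events, _ = simulate_divergence(
            f"(A:{blen},B:{blen});", 250, kappa=2.0, omega=0.1, seed=21
        )
        syn_events = sum(1 for e in events if e.cls == "synonymous")
        tab = saturation_scan(aln, include_outgroup=False)
        rows[blen] = (syn_events, float(tab.iloc[0].pS))
    # true synonymous event counts keep rising ...
    assert rows[6.0][0] > 4 * rows[0.3][0]
    # ... while observed pS saturates well below proportionality and below 1
    assert rows[6.0][1] < 1.0
    assert rows[6.0][1] < 4 * rows[0.3][1]


def test_neutral_means_agree_with_independent_coalescent_oracle():
    """Dual-route check of the neutral null: Tajima's D / Fu & Li D, F /
    Fay & Wu H means from this package's simulator + statistics match the
    same formulas applied to msprime tree sequences."""
    import msprime

    n, theta, reps = 20, 5.0, 1000
    # constants, written out independently of the package implementation
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    e1 = (b1 - 1 / a1) / a1
    e2 = (b2 - (n + 2) / (a1 * n) + a2 / a1**2) / (a1**2 + a2)
    an1 = a1 + 1.0 / n
    cn = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vD = 1 + (a1**2 / (a2 + a1**2)) * (cn - (n + 1) / (n - 1))
    uD = a1 - 1 - vD
    vF = (cn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (a1**2 + a2)
    uF = (
        1 + (n + 1) / (3 * (n - 1)) - 4 * ((n + 1) / (n - 1) ** 2) * (an1 - 2 * n / (n + 1))
    ) / a1 - vF

    oracle = {"D": [], "FD": [], "FF": [], "H": []}
    anc = msprime.sim_ancestry(
        samples=n, ploidy=1, sequence_length=1000, num_replicates=reps, random_seed=7
    )
    rng = np.random.default_rng(8)
    for ts in anc:
        mts = msprime.sim_mutations(
            ts,
            rate=theta / 2 / 1000,
            random_seed=int(rng.integers(1, 2**31)),
            model=msprime.BinaryMutationModel(),
        )
        S = mts.num_sites
        if S == 0:
            continue
        sfs = mts.allele_frequency_spectrum(polarised=True, span_normalise=False)
        i = np.arange(1, n)
        si = sfs[1:n]
        kbar = float((si * 2 * i * (n - i)).sum() / (n * (n - 1)))
        eta, eta_e = si.sum(), si[0]
        oracle["D"].append((kbar - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1)))
        oracle["FD"].append((eta - a1 * eta_e) / np.sqrt(uD * eta + vD * eta**2))
        oracle["FF"].append((kbar - eta_e) / np.sqrt(uF * eta + vF * eta**2))
        oracle["H"].append(kbar - float((2 * si * i**2).sum() / (n * (n - 1))))

    import hapsel as hp

    mine = {"D": [], "FD": [], "FF": [], "H": []}
    for i in range(reps):
        aln, _ = simulate_population(
            PopSimConfig(n=n, L_codons=300, theta=theta, seed=40_000 + i)
        )
        d = hp.tajima_D(aln)
        if not d.defined:
            continue
        mine["D"].append(d.value)
        dD, dF = hp.fu_li_D_F(aln)
        mine["FD"].append(dD.value)
        mine["FF"].append(dF.value)
        mine["H"].append(hp.fay_wu_H(aln).value)

    for key in oracle:
        # means compared on the scale of their Monte-Carlo standard error
        se = np.sqrt(
            np.var(oracle[key], ddof=1) / len(oracle[key])
            + np.var(mine[key], ddof=1) / len(mine[key])
        )
        assert abs(np.mean(oracle[key]) - np.mean(mine[key])) < 4 * se


def test_end_to_end_power_of_tip_interior_test_on_biased_data():
    hits = 0
    reps = 60
    for i in range(reps):
        _, truth = simulate_population(
            PopSimConfig(n=100, L_codons=500, theta=40, tip_bias=5.0, seed=3300 + i)
        )
        if templeton_fisher(truth.tip_interior_table()).p <= 0.05:
            hits += 1
    assert hits / reps >= 0.8
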