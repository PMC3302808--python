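# Methods

This note documents the statistical models, conventions and numerical
choices implemented in `hapsel`, and what the synthetic-data calibrations do
and do not establish.

## Sequence handling

Input is an aligned, in-frame nucleotide matrix over `{A,C,G,T,N,-}` with a
`frame_offset` locating the first complete codon; codon *i* (0-based) spans
nucleotides `frame_offset + 3i+1 … frame_offset + 3i+3` (1-based,
inclusive). Alignment columns containing a gap or `N` in any analyzed
sequence are excluded from every per-site statistic (and, for polarized
statistics, columns where the outgroup is gapped/ambiguous); the exclusion
list is reported by `site_diagnostics`. Region annotations are 1-based
inclusive nucleotide ranges; region subsets snap inward to complete codons.
A 541-column amplicon therefore analyzes exactly 180 codons — when a region
boundary convention is ambiguous (inclusive vs half-open), the analyzed
length is whatever the configured annotation yields, with 540 nt the
default expectation for the motivating amplicon.

Haplotypes are exact string-identity classes: an `N` never merges with a
resolved base. Identifiers `H1, H2, …` are assigned by descending count,
then lexicographic sequence, so collapsing is order-independent.

## Codon-level counting

`count_syn_nonsyn_sites` implements modified Nei–Gojobori site counting:
at each codon position a transition carries weight `R/(R+2)` and each
transversion `1/(R+2)` (`R=1` recovers the classic 1/3 weights; the
conventional default is `R=2`). Changes that would create a stop codon get
zero weight and the remaining weights at that position are renormalized —
stop-bearing variants are unobservable in a functional gene — which keeps
the invariant `s + a = 3` exact for every sense codon. No sense codon has a
position where all three changes are stops, so renormalization is always
well defined. Pairwise difference counts average over all substitution
orderings between two codons, excluding pathways through stop codons
(falling back to all pathways only if every one is blocked).

Synonymous/nonsynonymous nucleotide diversity divides pathway-averaged
difference counts by the pair-averaged synonymous/nonsynonymous site totals
over codons free of gaps, `N`s and stops, averaged over all sequence pairs.

## Neutrality statistics

All formulas use the standard constants: Tajima's
`D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1))`; Fu & Li's `D` and `F` from the total
polarized mutation count η and the derived-singleton count η_e with the
1993 variance coefficients; Fay & Wu's `H = k̄ − θ_H`,
`θ_H = Σ 2·S_i·i²/(n(n−1))`. Ancestral states are taken from the outgroup
allele; segregating sites where the outgroup carries an allele absent from
the sample (a third allele) are excluded from polarized statistics and
counted in diagnostics. With `S = 0` each statistic is reported as
explicitly undefined, never as zero.

Scales: Hd dimensionless, π and θ per site, `H` per gene by default (the
scale on which published tables print it; a per-site flag exists).
Tajima's `D` p-value uses the bounded-beta approximation (support
`[(2/n − 1/a₁)/√e₂, (n/(2(n−1)) − 1/a₁)/√e₂]`, mean 0, variance 1); Fu &
Li's statistics use the normal tail, which is adequate for the
significance-star use these tests get here. Multiple tests are corrected by
Holm's step-down with Dunn–Šidák thresholds
`1 − (1−α)^{1/(m−i+1)}`; adjusted p-values use the matching monotone
step-down transform.

Calibration: over 2000 neutral coalescent replicates (n=20, θ=5) the means
of D, Fu & Li's D/F and H all fall within ±0.1 of zero, and a dual-route
test checks that the same formulas applied to `msprime` tree sequences give
matching means — these statistics are genuinely slightly negatively biased
at this sample size (ratio statistics conditioned on S ≥ 1), which the
±0.1 band absorbs.

## Statistical parsimony network

The connection limit is the largest number of steps *j* whose probability
of parsimony is ≥ 0.95. That probability is computed from a Poisson
multiple-hit model: with *j* observed differences over *L* usable sites,
the per-site change count is Poisson with rate `λ = −ln(1 − j/L)`, a
differing site changed exactly once with probability `λe^{−λ}/(1−e^{−λ})`,
and the *j* differences are treated as independent. For L=540 this yields a
limit of 7 steps. This is a transparent stand-in for the original 1992
recursion — the criterion ("no multiple substitution at a connecting step,
at 95% confidence") is the same, the arithmetic simpler; an explicit user
override is accepted wherever the limit is consumed.

Construction is agglomerative: all distance-1 edges first (an edge closing
a cycle is kept and flagged ambiguous — loops are retained, not resolved,
by default), then components merge in order of increasing distance, always
through the closest pair of current nodes *including previously inferred
intermediates*, instantiating d−1 inferred nodes per d-step merge (sites
mutated in ascending position order). After each merge, newly created
intermediates contribute distance-1 adjacencies before the next merge.
Components farther apart than the limit remain unconnected, as in the
original method. All tie-breaks are deterministic (distance, then node id),
so a permuted input yields an identical network.

Rooting: the observed haplotype with minimal distance to the outgroup
(ties: higher count, then smaller id). Bridge edges are oriented away from
the root; edges inside loops cannot be polarized and are flagged. Each
oriented edge becomes a mutation record: its codon context is read from the
ancestral node's full sequence (so successive hits in one codon are
classified sequentially), and it is *tip* iff the derived-side component
contains exactly one **observed** haplotype — inferred intermediates never
count. Note a consequence used in the tests: a 4-haplotype path rooted at
an end has one tip mutation, rooted at an interior node it has two.

Known limitation: distance-based agglomeration joins sister clades directly
instead of through their unsampled common ancestor, which misorients the
private mutations of the nearer endpoint and dilutes tip/interior signal
relative to the true genealogy (measured directly against simulator truth:
orientation error ~20–37% depending on θ). This is intrinsic to the method
class; consumers who need maximal power should feed the contingency test
from a better-resolved genealogy when one is available.

## Network selection tests

*Tip/interior contingency*: the 2×2 table (position × class) is tested with
the two-sided Fisher exact probability under the point-probability
convention — the sum of hypergeometric probabilities not exceeding that of
the observed table (stated explicitly because two-sided Fisher conventions
differ). The implementation is an in-package hypergeometric sum; tests
cross-check it against exhaustive enumeration and `scipy`.

*Stratified homogeneity*: for R×C tables (position × class-within-region),
a margin-preserving Monte-Carlo permutation test: column labels are
permuted against fixed row blocks, tables are ordered by Pearson χ², and
`p = (1 + #{χ²_perm ≥ χ²_obs})/(n_perm + 1)` — never zero, reproducible for
a given seed. 1000 replicates is the interactive default; calibration runs
use ≥10⁵.

*Mutation survival*: interior mutations present in at least
`min_haplotypes` (default 3) observed haplotypes are ranked by their
derived-haplotype counts, synonymous vs nonsynonymous. The test statistic
is the continuity-corrected standardized Mann–Whitney U for the
nonsynonymous group; the continuity correction is half the lattice spacing
of U (0.25 when midrank ties are present, 0.5 otherwise). The p-value is,
in order of preference: exact enumeration of all C(m+n, m) rank splits
whenever m+n ≤ 14; otherwise the Edgeworth-improved normal tail
`Φ̄(z) + φ(z)(γ₂/24)(z³−3z)` with the exact excess kurtosis
`γ₂ = −(6/5)(m²+n²+mn+m+n)/(mn(N+1))` and tie-corrected variance. On
untied data the improved tail matches exact enumeration to < 0.01; with
heavy ties at tiny m, n the exact null is lumpy and only the exact path is
authoritative (which is why it is the default there). The min-haplotype
filter applies only to this test, not to the contingency tests.

A McDonald–Kreitman gate (`mcdonald_kreitman_feasible`) reports the count
of fixed interspecific differences and declines to compute the test when
there are none — the situation in samples without reciprocal monophyly.

## Physicochemical scan

Ancestral sequences come from per-site Fitch parsimony with a deterministic
resolution (root: smallest state in A<C<G<T order; children keep the
parent's state when possible); an injection point accepts externally
computed ancestral sequences instead. Every branch codon change with a
changed amino acid becomes a replacement event; events through reconstructed
stop codons are skipped.

For each property, replacement magnitude `|prop(aa_to) − prop(aa_from)|` is
graded into k (default 3) equal-width categories over the property's full
replacement range (all 190 unordered amino-acid pairs). The neutral
expectation is the uniform enumeration of all possible single-nucleotide
nonsynonymous changes (stops excluded) over the pooled codon composition of
the reconstructed node sequences; a branch-length-weighted expectation can
be supplied through the `expected_probs` hook. Per category,
`z = (O − E)/√(E(1 − E/N))` under the binomial model with N events,
two-sided normal p, Bonferroni across properties × categories. Significant
positive z in category k flags positive-destabilizing selection; in
category 1, positive-stabilizing; significant negative z, a purifying
signal. The goodness-of-fit χ² over categories (df = k−1) screens global
deviation first.

Sliding windows of 20 codons (step 1) recompute the radical-category z per
window for the properties already flagged; the significance limit is the
two-sided normal quantile at `0.05/(number of windows)` — for 180 codons,
161 windows and a limit of z ≈ 3.61.

The bundled property table is a curated set of 12 standard published
amino-acid indices (Grantham polarity and volume, Kyte–Doolittle
hydropathy, Hopp–Woods hydrophilicity, Zimmerman polarity and isoelectric
point, net/positive/negative charge, pK₁, molecular weight, Chou–Fasman
helix propensity), keyed by accession; `PropertyTable.from_tsv` accepts any
user table with 20 values per property, so the full 51-property panel of
the original workflow can be dropped in when available. Calibration: with
events drawn from the neutral enumeration itself, ≤1% of property tests
flag destabilizing selection at the Bonferroni-corrected 5% level over 500
simulated datasets.

## MaxChi

For each sequence pair, the alignment is reduced to the sites polymorphic
in the full sample; every internal breakpoint of the pair's match/mismatch
vector yields a 2×2 χ² of (match/mismatch × left/right), unwindowed. The
null permutes site order (1000 replicates by default, `+1`-corrected p,
seeded). Pairs with fewer than 4 informative sites, identical pairs, and
all-mismatch pairs are skipped with notice. On a constructed recombinant
the junction is localized within ±2 polymorphic sites with p ≤ 0.01; on
clonal coalescent data the rejection rate at the 0.05 cutoff sits at or
slightly below nominal (the permutation null is mildly conservative under
the mosaic of shared genealogy). The pipeline exposes the screen as a gate:
a hit produces a warning banner (network tests assume no recombination) but
does not halt the run.

## Synthetic data

`simulate_population`: Kingman coalescent for n lineages (exponential
waiting times, rate k(k−1)/2), Poisson mutations per branch with mean
(θ/2)·length, infinite sites at the nucleotide level — each mutation claims
a fresh codon, drawn uniformly among those still free that admit a change
of the requested class. Class assignment: a mutation on a branch with
weight w (= `tip_bias` on external branches, 1 on internal) is
nonsynonymous with probability `f·w/(f·w + (1−f))`, `f` the target
nonsynonymous fraction (default 0.5); `tip_bias = 1` is neutral,
`tip_bias > 1` mimics purifying selection by concentrating amino-acid
changes on young branches. The ancestral sequence (uniform random sense
codons) is emitted as the outgroup, making polarization exact. The truth
record carries every mutation's branch, external flag, site, class and
descendant-leaf count, and replaying it reproduces the emitted sequences
exactly.

What the generator deliberately does not emulate: recombination,
demographic structure or growth, mutation-rate heterogeneity along the
sequence, back/parallel mutation (population scale), and selection acting
through genealogy distortion — the tip-bias knob moves mutation placement,
not the genealogy, because the tests under study consume exactly the
tip/interior × class structure and the knob gives analytic control of the
alternative. Passing calibrations therefore validate the statistics and
their null distributions, not robustness to demography — the motivating
study itself notes that demography can mimic these signals.

`simulate_divergence`: continuous-time codon substitution along a fixed
tree (Gillespie per branch); single-nucleotide moves at relative rate κ for
transitions, ×ω for nonsynonymous changes, 0 into stops; ω may vary per
codon. Multiple hits are allowed — this is what makes synonymous saturation
observable in the pS-vs-divergence scan.

Seeding: one integer seed feeds `numpy.random.SeedSequence`; every emitted
object is bit-reproducible for a given configuration.

## Problem sizes used in the shipped calibrations

Neutral means: 2000 replicates at n=20, θ=5. Contingency-test calibration:
1000 neutral and 500 tip-bias-5 replicates at n=100, θ=40 (~200 mutations,
the scale of the motivating data), reading the position × class table from
the simulator's truth record (the quantity the test consumes; rebuilding a
network per replicate adds reconstruction noise that is assessed separately
and documented above). E[S] recovery: 2000 replicates. Physicochemical
false-flag rate: 500 datasets × 100 events. MaxChi: 500 clonal replicates,
500–2000 permutations. The full suite runs in about a minute on one CPU.
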