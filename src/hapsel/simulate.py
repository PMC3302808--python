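"""Synthetic data with known selection structure.

Two generators:

* :func:`simulate_population` draws a Kingman coalescent genealogy for n
  lineages, scatters mutations on branches (Poisson, rate theta/2 per unit
  coalescent time), classifies each as synonymous or nonsynonymous with a
  tunable *tip bias* that concentrates nonsynonymous changes on external
  branches (mimicking purifying selection against young deleterious
  variants), and realizes each mutation as a concrete codon change at a
  fresh codon (infinite sites at the nucleotide level).  The ancestral
  sequence is emitted as the outgroup.
* :func:`simulate_divergence` runs a continuous-time codon substitution
  process (single-nucleotide moves, transition bias kappa, per-codon omega,
  zero rate into stops) along a fixed Newick tree, for divergence-scale
  fixtures; multiple hits are allowed, which is what makes saturation
  observable.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning, so every emitted object is
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codons import (
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    is_transition,
    single_nt_neighbors,
    translate,
)
from .seqdata import CodonAlignment, SampleSequence


@dataclass
class PopSimConfig:
    n: int = 20
    L_codons: int = 180
    theta: float = 5.0
    tip_bias: float = 1.0
    nonsyn_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n >= 2 required")
        if self.theta <= 0 or self.tip_bias <= 0:
            raise ValueError("theta and tip_bias must be positive")
        if not 0 <= self.nonsyn_fraction <= 1:
            raise ValueError("nonsyn_fraction must be in [0, 1]")


@dataclass
class SimMutation:
    branch: int  # branch id = id of the node below the branch
    external: bool
    site: int  # 1-based nt position
    codon_index: int
    cls: str  # "synonymous" | "nonsynonymous"
    codon_from: str
    codon_to: str
    n_descendants: int  # leaves below the branch


@dataclass
class SimTruth:
    newick: str
    ancestral_seq: str
    mutations: list[SimMutation]
    S: int
    branch_lengths: dict[int, float] = field(default_factory=dict)

    def tip_interior_table(self) -> np.ndarray:
        """[[tip syn, tip nonsyn], [interior syn, interior nonsyn]]."""
        t = np.zeros((2, 2), dtype=int)
        for m in self.mutations:
            t[0 if m.external else 1, 0 if m.cls == "synonymous" else 1] += 1
        return t

    def survival_counts(self, interior_only: bool = True):
        syn, nonsyn = [], []
        for m in self.mutations:
            if interior_only and m.external:
                continue
            (syn if m.cls == "synonymous" else nonsyn).append(m.n_descendants)
        return syn, nonsyn


# ---------------------------------------------------------------------------
# population simulator
# ---------------------------------------------------------------------------
def _kingman_branches(n: int, rng: np.random.Generator):
    """Coalescent genealogy; returns (branches, children, newick).

    Nodes 0..n-1 are leaves.  Each branch is (node, length, n_desc,
    external); children maps internal node -> (a, b).
    """
    active = list(range(n))
    t_of = {i: 0.0 for i in range(n)}
    n_desc = {i: 1 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    t = 0.0
    nxt = n
    parent_time: dict[int, float] = {}
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        for c in (a, b):
            parent_time[c] = t
        children[nxt] = (a, b)
        t_of[nxt] = t
        n_desc[nxt] = n_desc[a] + n_desc[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    branches = []
    for node, t0 in t_of.items():
        if node == root:
            continue
        branches.append((node, parent_time[node] - t0, n_desc[node], node < n))

    def nwk(node) -> str:
        if node < n:
            core = f"s{node + 1}"
        else:
            a, b = children[node]
            core = f"({nwk(a)},{nwk(b)})"
        if node == root:
            return core
        return f"{core}:{parent_time[node] - t_of[node]:.6f}"

    return branches, children, nwk(root) + ";", root


def _random_coding_sequence(L_codons: int, rng: np.random.Generator) -> str:
    sense = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
    return "".join(np.asarray(sense)[rng.integers(len(sense), size=L_codons)])


def _sample_change(codon: str, cls: str, rng: np.random.Generator):
    """A concrete single-nt change of *codon* with the requested class, or
    None if the codon admits none."""
    opts = []
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            syn = translate(mut) == translate(codon)
            if (cls == "synonymous") == syn:
                opts.append((pos, mut))
    if not opts:
        return None
    return opts[int(rng.integers(len(opts)))]


def simulate_population(cfg: PopSimConfig) -> tuple[CodonAlignment, SimTruth]:
    """Coalescent sample of coding haplotypes with tunable tip bias.

    A mutation on a branch with weight w (= tip_bias on external branches, 1
    on internal ones) is nonsynonymous with probability
    ``f*w / (f*w + (1-f))`` where f is ``nonsyn_fraction``; with tip_bias = 1
    the process is neutral with a class-blind placement.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    branches, children, newick, root = _kingman_branches(cfg.n, rng)
    anc = _random_coding_sequence(cfg.L_codons, rng)
    codons = [anc[3 * i : 3 * i + 3] for i in range(cfg.L_codons)]
    free = list(range(cfg.L_codons))
    f = cfg.nonsyn_fraction
    mutations: list[SimMutation] = []
    for node, blen, ndesc, external in branches:
        n_mut = rng.poisson(cfg.theta / 2.0 * blen)
        for _ in range(n_mut):
            w = cfg.tip_bias if external else 1.0
            denom = f * w + (1.0 - f)
            cls = "nonsynonymous" if rng.random() < f * w / denom else "synonymous"
            placed = False
            order = rng.permutation(len(free))
            for oi in order:
                ci = free[oi]
                got = _sample_change(codons[ci], cls, rng)
                if got is None:
                    continue
                pos, mut_codon = got
                mutations.append(
                    SimMutation(
                        branch=node,
                        external=external,
                        site=3 * ci + pos + 1,
                        codon_index=ci,
                        cls=cls,
                        codon_from=codons[ci],
                        codon_to=mut_codon,
                        n_descendants=ndesc,
                    )
                )
                free.pop(int(oi))
                placed = True
                break
            if not placed:
                raise ValueError(
                    "L_codons too small to place all mutations under infinite sites; "
                    "increase L_codons"
                )

    # realize sequences by replaying mutations root -> leaf
    muts_by_branch: dict[int, list[SimMutation]] = {}
    for m in mutations:
        muts_by_branch.setdefault(m.branch, []).append(m)

    seqs: dict[int, str] = {}

    def walk(node: int, seq: str):
        for m in muts_by_branch.get(node, []):
            a0 = 3 * m.codon_index
            seq = seq[:a0] + m.codon_to + seq[a0 + 3 :]
        if node < cfg.n:
            seqs[node] = seq
        else:
            for c in children[node]:
                walk(c, seq)

    if root < cfg.n:  # n == 1 never happens (n >= 2)
        seqs[root] = anc
    else:
        for c in children[root]:
            walk(c, anc)

    records = [
        SampleSequence(sample_id=f"s{i + 1}", seq=seqs[i], species="sim")
        for i in range(cfg.n)
    ]
    aln = CodonAlignment(records, frame_offset=0, outgroup=("outgroup", anc))
    truth = SimTruth(
        newick=newick,
        ancestral_seq=anc,
        mutations=mutations,
        S=len({m.site for m in mutations}),
        branch_lengths={b[0]: b[1] for b in branches},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# divergence simulator
# ---------------------------------------------------------------------------
@dataclass
class DivergenceEvent:
    branch: tuple[str, str]
    codon_index: int
    codon_from: str
    codon_to: str
    cls: str
    is_transition: bool
    time: float


def _codon_rates(codon: str, kappa: float, omega: float):
    out = []
    total = 0.0
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            r = kappa if is_transition(codon[pos], alt) else 1.0
            syn = translate(mut) == translate(codon)
            if not syn:
                r *= omega
            if r > 0:
                out.append((mut, r, syn))
                total += r
    return out, total


def simulate_divergence(
    tree: dendropy.Tree | str,
    L_codons: int,
    kappa: float = 2.0,
    omega=0.2,
    seed: int = 0,
    root_seq: str | None = None,
):
    """Gillespie codon substitution along a tree with branch lengths in
    expected substitutions per codon under the baseline (synonymous
    transversion) rate.  ``omega`` may be a scalar or a per-codon array.
    Returns (CodonAlignment of the leaves, events list, tree)."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    omega_arr = np.full(L_codons, float(omega)) if np.isscalar(omega) else np.asarray(omega, float)
    if omega_arr.size != L_codons or (omega_arr < 0).any():
        raise ValueError("omega must be scalar or length L_codons, nonnegative")
    if root_seq is None:
        root_seq = _random_coding_sequence(L_codons, rng)
    n_label = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.hapsel_label = nd.taxon.label
        else:
            n_label += 1
            nd.hapsel_label = nd.label or f"node{n_label}"
    events: list[DivergenceEvent] = []
    states: dict[str, str] = {}

    def evolve(seq: str, blen: float, branch) -> str:
        codons = [seq[3 * i : 3 * i + 3] for i in range(L_codons)]
        rates = []
        totals = np.zeros(L_codons)
        for i, c in enumerate(codons):
            r, tot = _codon_rates(c, kappa, omega_arr[i])
            rates.append(r)
            totals[i] = tot
        t = 0.0
        while True:
            R = totals.sum()
            if R <= 0:
                break
            t += rng.exponential(1.0 / R)
            if t > blen:
                break
            ci = int(rng.choice(L_codons, p=totals / R))
            opts = rates[ci]
            ws = np.array([o[1] for o in opts])
            k = int(rng.choice(len(opts), p=ws / ws.sum()))
            mut, _, syn = opts[k]
            events.append(
                DivergenceEvent(
                    branch=branch,
                    codon_index=ci,
                    codon_from=codons[ci],
                    codon_to=mut,
                    cls="synonymous" if syn else "nonsynonymous",
                    is_transition=sum(a != b for a, b in zip(codons[ci], mut)) == 1
                    and is_transition(
                        *[(a, b) for a, b in zip(codons[ci], mut) if a != b][0]
                    ),
                    time=t,
                )
            )
            codons[ci] = mut
            r, tot = _codon_rates(mut, kappa, omega_arr[ci])
            rates[ci] = r
            totals[ci] = tot
        return "".join(codons)

    root = tree.seed_node
    states[root.hapsel_label] = root_seq
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        blen = nd.edge.length or 0.0
        states[nd.hapsel_label] = evolve(
            states[nd.parent_node.hapsel_label],
            blen,
            (nd.parent_node.hapsel_label, nd.hapsel_label),
        )
    leaf_records = [
        SampleSequence(sample_id=nd.hapsel_label, seq=states[nd.hapsel_label])
        for nd in tree.leaf_node_iter()
    ]
    aln = CodonAlignment(leaf_records, frame_offset=0, outgroup=("root", root_seq))
    return aln, events, tree
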