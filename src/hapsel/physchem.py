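"""Detection of positive-destabilizing and stabilizing selection from
amino-acid physicochemical property changes along a phylogeny.

Workflow: reconstruct ancestral sequences at every internal node (Fitch
parsimony by default, or inject externally computed states), enumerate the
amino-acid replacements implied on each branch, grade each replacement's
property change into k equal-width magnitude categories (conservative ->
radical), and compare observed category counts with the expectation under a
uniform enumeration of all possible single-nucleotide nonsynonymous changes
over the reconstructed codon composition.  A significant positive z-score in
the most radical category flags positive-destabilizing selection; in the
most conservative category, positive-stabilizing (purifying-compatible)
selection.  A 20-codon sliding window localizes the signal.

The bundled property table is a curated subset of standard published
amino-acid indices (Grantham polarity and volume, Kyte-Doolittle hydropathy,
charge, isoelectric point, ...), keyed by accession; any AAindex-style table
with 20 values per property can be supplied instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps

from .codons import (
    GENETIC_CODE,
    NUCLEOTIDES,
    STOP_CODONS,
    single_nt_neighbors,
    translate,
)
from .seqdata import CodonAlignment

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# property table
# ---------------------------------------------------------------------------
@dataclass
class PropertyTable:
    properties: dict[str, dict[str, float]]  # accession -> {aa: value}
    names: dict[str, str]
    k: int = 3

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need at least 2 magnitude categories")
        for acc, vals in self.properties.items():
            if set(vals) != set(AA_ORDER):
                raise ValueError(f"property {acc} must map all 20 amino acids")

    @property
    def accessions(self) -> list[str]:
        return list(self.properties)

    def magnitude(self, acc: str, aa_from: str, aa_to: str) -> float:
        v = self.properties[acc]
        return abs(v[aa_to] - v[aa_from])

    def max_magnitude(self, acc: str) -> float:
        cache = self.__dict__.setdefault("_max_mag", {})
        if acc not in cache:
            v = self.properties[acc]
            cache[acc] = max(
                abs(v[a] - v[b]) for a, b in itertools.combinations(AA_ORDER, 2)
            )
        return cache[acc]

    def category(self, acc: str, aa_from: str, aa_to: str) -> int:
        """Equal-width magnitude category in 1..k over the property's full
        replacement range (all 190 unordered amino-acid pairs)."""
        cache = self.__dict__.setdefault("_cat", {})
        key = (acc, aa_from, aa_to)
        if key not in cache:
            width = self.max_magnitude(acc) / self.k
            mag = self.magnitude(acc, aa_from, aa_to)
            cache[key] = 1 if width == 0 else min(self.k, max(1, math.ceil(mag / width)))
        return cache[key]

    @classmethod
    def from_tsv(cls, path_or_buf, k: int = 3) -> "PropertyTable":
        df = pd.read_csv(path_or_buf, sep="\t")
        props, names = {}, {}
        for _, row in df.iterrows():
            acc = row["accession"]
            props[acc] = {aa: float(row[aa]) for aa in AA_ORDER}
            names[acc] = str(row.get("name", acc))
        return cls(props, names, k=k)

    @classmethod
    def bundled(cls, k: int = 3) -> "PropertyTable":
        with resources.files("hapsel.data").joinpath("aa_properties.tsv").open() as fh:
            return cls.from_tsv(fh, k=k)


# ---------------------------------------------------------------------------
# ancestral states (Fitch parsimony)
# ---------------------------------------------------------------------------
_ORDER = {b: i for i, b in enumerate(NUCLEOTIDES)}  # deterministic tie-break A<C<G<T


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string (or file contents) into a dendropy Tree."""
    return dendropy.Tree.get(data=newick, schema="newick")


def fitch_ancestral(aln: CodonAlignment, tree: dendropy.Tree | str) -> dict[str, str]:
    """Fitch-parsimony ancestral sequences at every node of *tree*.

    Bottom-up state sets per site, then a deterministic top-down resolution:
    the root takes the smallest state in A<C<G<T order; a child keeps its
    parent's state when possible, otherwise the smallest of its own set.
    Returns a mapping from node label to full sequence; internal nodes
    without labels get generated labels ``node<i>`` (also written back onto
    the tree).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    by_id = {r.sample_id: r.seq for r in aln.sequences}
    leaves = [lf for lf in tree.leaf_node_iter()]
    missing = [lf.taxon.label for lf in leaves if lf.taxon.label not in by_id]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {missing}")
    L = aln.length
    n_label = itertools.count(1)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.hapsel_label = nd.taxon.label
        else:
            nd.hapsel_label = nd.label or f"node{next(n_label)}"

    post = list(tree.postorder_node_iter())
    sets: dict[int, list[set]] = {}
    for nd in post:
        if nd.is_leaf():
            sets[id(nd)] = [
                {b} if b in _ORDER else set(NUCLEOTIDES)
                for b in by_id[nd.taxon.label]
            ]
        else:
            kids = [sets[id(c)] for c in nd.child_nodes()]
            merged = []
            for j in range(L):
                inter = set.intersection(*(k[j] for k in kids))
                merged.append(inter if inter else set.union(*(k[j] for k in kids)))
            sets[id(nd)] = merged

    states: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        s = sets[id(nd)]
        if nd.parent_node is None:
            seq = "".join(min(x, key=_ORDER.get) for x in s)
        else:
            pseq = states[nd.parent_node.hapsel_label]
            seq = "".join(
                pseq[j] if pseq[j] in s[j] else min(s[j], key=_ORDER.get)
                for j in range(L)
            )
        states[nd.hapsel_label] = seq
    return states


# ---------------------------------------------------------------------------
# replacement events
# ---------------------------------------------------------------------------
@dataclass
class ReplacementEvent:
    branch: tuple[str, str]  # (parent label, child label)
    codon_index: int
    aa_from: str
    aa_to: str
    magnitudes: dict[str, float] = field(default_factory=dict)
    categories: dict[str, int] = field(default_factory=dict)


def enumerate_replacements(
    states: dict[str, str],
    tree: dendropy.Tree | str,
    props: PropertyTable,
    frame_offset: int = 0,
) -> list[ReplacementEvent]:
    """Amino-acid replacements implied on every branch by the ancestral
    states.  Codons reconstructed as stops are skipped (rare parsimony
    artifacts)."""
    if isinstance(tree, str) or not hasattr(
        next(tree.preorder_node_iter()), "hapsel_label"
    ):
        raise ValueError(
            "pass the same dendropy Tree object previously given to fitch_ancestral"
        )
    events: list[ReplacementEvent] = []
    L = len(next(iter(states.values())))
    n_codons = (L - frame_offset) // 3
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        pseq = states[nd.parent_node.hapsel_label]
        cseq = states[nd.hapsel_label]
        for ci in range(n_codons):
            a0 = frame_offset + 3 * ci
            ca, cb = pseq[a0 : a0 + 3], cseq[a0 : a0 + 3]
            if ca == cb or not (set(ca + cb) <= set("ACGT")):
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            aa_a, aa_b = translate(ca), translate(cb)
            if aa_a == aa_b:
                continue
            ev = ReplacementEvent(
                branch=(nd.parent_node.hapsel_label, nd.hapsel_label),
                codon_index=ci,
                aa_from=aa_a,
                aa_to=aa_b,
            )
            for acc in props.accessions:
                ev.magnitudes[acc] = props.magnitude(acc, aa_a, aa_b)
                ev.categories[acc] = props.category(acc, aa_a, aa_b)
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# expected category distribution and the category z-test
# ---------------------------------------------------------------------------
def codon_composition(states: dict[str, str], frame_offset: int = 0) -> dict[str, int]:
    """Pooled codon counts over all reconstructed node sequences."""
    comp: dict[str, int] = {}
    for seq in states.values():
        for a0 in range(frame_offset, len(seq) - 2, 3):
            c = seq[a0 : a0 + 3]
            if set(c) <= set("ACGT") and c not in STOP_CODONS:
                comp[c] = comp.get(c, 0) + 1
    return comp


def possible_nonsyn_changes(codon: str) -> list[tuple[str, str]]:
    """(aa_from, aa_to) for each single-nucleotide nonsynonymous change of
    *codon* that does not create a stop."""
    out = []
    aa0 = GENETIC_CODE[codon]
    for nb in single_nt_neighbors(codon):
        if nb in STOP_CODONS:
            continue
        aa1 = GENETIC_CODE[nb]
        if aa1 != aa0:
            out.append((aa0, aa1))
    return out


def expected_category_probs(
    props: PropertyTable, composition: dict[str, int], codon_indices=None
) -> dict[str, np.ndarray]:
    """Neutral expected distribution over magnitude categories per property:
    the uniform enumeration of all possible single-nt nonsynonymous changes,
    weighted by codon multiplicity in the composition."""
    per_acc = {acc: np.zeros(props.k) for acc in props.accessions}
    total = 0
    for codon, mult in composition.items():
        changes = possible_nonsyn_changes(codon)
        total += mult * len(changes)
        for aa_a, aa_b in changes:
            for acc in props.accessions:
                per_acc[acc][props.category(acc, aa_a, aa_b) - 1] += mult
    if total == 0:
        raise ValueError("composition admits no nonsynonymous change")
    return {acc: v / v.sum() for acc, v in per_acc.items()}


def sample_neutral_events(
    props: PropertyTable,
    composition: dict[str, int],
    n_events: int,
    rng: np.random.Generator,
    codon_index_range: tuple[int, int] | None = None,
) -> list["ReplacementEvent"]:
    """Draw replacement events from the neutral enumeration itself: codons
    weighted by multiplicity, changes uniform among each codon's possible
    single-nt nonsynonymous changes.  Used for calibration."""
    pool: list[tuple[str, str]] = []
    for codon, mult in composition.items():
        pool.extend(possible_nonsyn_changes(codon) * mult)
    idx = rng.integers(len(pool), size=n_events)
    lo, hi = codon_index_range or (0, 1)
    events = []
    for i in idx:
        aa_a, aa_b = pool[int(i)]
        ev = ReplacementEvent(
            branch=("sim", "sim"),
            codon_index=int(rng.integers(lo, hi)),
            aa_from=aa_a,
            aa_to=aa_b,
        )
        for acc in props.accessions:
            ev.magnitudes[acc] = props.magnitude(acc, aa_a, aa_b)
            ev.categories[acc] = props.category(acc, aa_a, aa_b)
        events.append(ev)
    return events


@dataclass
class MM01Result:
    accession: str
    name: str
    n_events: int
    observed: np.ndarray
    expected: np.ndarray
    gof_chi2: float
    gof_p: float
    z: np.ndarray  # per category
    p: np.ndarray  # two-sided per category
    p_bonferroni: np.ndarray
    verdicts: list[str]


def mm01_test(
    events: list[ReplacementEvent],
    props: PropertyTable,
    composition: dict[str, int],
    alpha: float = 0.05,
    expected_probs: dict[str, np.ndarray] | None = None,
) -> list[MM01Result]:
    """Category goodness-of-fit and per-category z-scores per property.

    z = (O - E)/sqrt(E (1 - E/N)) under the binomial model with N events;
    Bonferroni correction spans properties x categories.  Verdict reading:
    significant positive z in the most radical category ->
    positive_destabilizing; in category 1 -> positive_stabilizing;
    significant negative z -> purifying_signal; otherwise neutral.
    """
    if not events:
        raise ValueError("no replacement events: MM01 not computable")
    exp_probs = expected_probs or expected_category_probs(props, composition)
    k = props.k
    n_tests = len(props.accessions) * k
    out = []
    N = len(events)
    for acc in props.accessions:
        obs = np.zeros(k)
        for ev in events:
            obs[ev.categories[acc] - 1] += 1
        E = exp_probs[acc] * N
        nz = E > 0
        gof = float((((obs - E) ** 2)[nz] / E[nz]).sum())
        gof_p = float(sps.chi2.sf(gof, df=max(int(nz.sum()) - 1, 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(nz, (obs - E) / np.sqrt(E * (1.0 - E / N)), 0.0)
        z = np.nan_to_num(z)
        p = 2.0 * sps.norm.sf(np.abs(z))
        p_b = np.minimum(1.0, p * n_tests)
        verdicts = []
        for ci in range(k):
            if p_b[ci] <= alpha and z[ci] > 0 and ci == k - 1:
                verdicts.append("positive_destabilizing")
            elif p_b[ci] <= alpha and z[ci] > 0 and ci == 0:
                verdicts.append("positive_stabilizing")
            elif p_b[ci] <= alpha and z[ci] < 0:
                verdicts.append("purifying_signal")
            else:
                verdicts.append("neutral")
        out.append(
            MM01Result(
                accession=acc,
                name=props.names.get(acc, acc),
                n_events=N,
                observed=obs,
                expected=E,
                gof_chi2=gof,
                gof_p=gof_p,
                z=z,
                p=p,
                p_bonferroni=p_b,
                verdicts=verdicts,
            )
        )
    return out


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------
@dataclass
class WindowScan:
    starts: np.ndarray  # 0-based first codon of each window
    z: dict[str, np.ndarray]  # accession -> per-window radical-category z
    threshold: float  # Bonferroni-corrected two-sided z limit
    window: int
    flagged: dict[str, np.ndarray]


def sliding_window(
    events: list[ReplacementEvent],
    props: PropertyTable,
    significant_properties: list[str],
    n_codons: int,
    composition: dict[str, int],
    window: int = 20,
    step: int = 1,
    alpha: float = 0.05,
) -> WindowScan:
    """Radical-category z-scores in 20-codon windows (step 1) for the
    properties already flagged destabilizing; the significance limit is the
    two-sided normal quantile at alpha / (number of windows)."""
    if n_codons < window:
        raise ValueError("alignment shorter than one window")
    starts = np.arange(0, n_codons - window + 1, step)
    n_win = len(starts)
    thr = float(sps.norm.isf(alpha / 2.0 / n_win))
    exp_probs = expected_category_probs(props, composition)
    k = props.k
    zmap, flagged = {}, {}
    ev_by_codon: dict[int, list[ReplacementEvent]] = {}
    for ev in events:
        ev_by_codon.setdefault(ev.codon_index, []).append(ev)
    for acc in significant_properties:
        zs = np.zeros(n_win)
        for w, s0 in enumerate(starts):
            evs = [e for ci in range(s0, s0 + window) for e in ev_by_codon.get(ci, [])]
            N = len(evs)
            if N == 0:
                continue
            obs_k = sum(1 for e in evs if e.categories[acc] == k)
            E = exp_probs[acc][k - 1] * N
            denom = math.sqrt(E * (1.0 - E / N)) if 0 < E < N else 0.0
            zs[w] = (obs_k - E) / denom if denom > 0 else 0.0
        zmap[acc] = zs
        flagged[acc] = zs > thr
    return WindowScan(starts=starts, z=zmap, threshold=thr, window=window, flagged=flagged)


def results_table(results: list[MM01Result]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "accession": r.accession,
                "property": r.name,
                "n_events": r.n_events,
                "gof_chi2": r.gof_chi2,
                "gof_p": r.gof_p,
                **{f"z_cat{i + 1}": r.z[i] for i in range(len(r.z))},
                **{f"verdict_cat{i + 1}": r.verdicts[i] for i in range(len(r.z))},
            }
        )
    return pd.DataFrame(rows)
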