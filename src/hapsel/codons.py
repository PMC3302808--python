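"""Codon-level substitution classification and synonymous/nonsynonymous site counting.

Everything downstream (diversity partitioned by site class, the network edge
labels, the physicochemical scan, the simulators) shares this module's view of
the standard nuclear genetic code.
"""

from __future__ import annotations

import enum
import itertools
from functools import lru_cache

NUCLEOTIDES = "ACGT"

# Standard nuclear genetic code, codon -> one-letter amino acid, '*' = stop.
GENETIC_CODE: dict[str, str] = {}
_BASES = ("T", "C", "A", "G")
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SubstitutionClass(enum.Enum):
    """Classification of a codon-to-codon change under the standard code."""

    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    STOP_INVOLVING = "stop_involving"
    MULTI_HIT = "multi_hit"
    AMBIGUOUS = "ambiguous"


class CodonError(ValueError):
    pass


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise CodonError(f"invalid codon {codon!r}: expected 3 nt over ACGT")
    return codon


def translate(codon: str) -> str:
    """One-letter amino acid for *codon* ('*' for stop)."""
    return GENETIC_CODE[_check_codon(codon)]


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def classify_substitution(codon_from: str, codon_to: str) -> SubstitutionClass:
    """Classify a single codon change.

    One differing position: synonymous iff the amino acid is unchanged; any
    stop codon at either end makes the change ``STOP_INVOLVING``.  More than
    one differing position is ``MULTI_HIT`` (pathway-dependent; see
    :func:`pairwise_differences`).  Identical codons are not a substitution.
    """
    a, b = _check_codon(codon_from), _check_codon(codon_to)
    ndiff = sum(x != y for x, y in zip(a, b))
    if ndiff == 0:
        raise CodonError("codons are identical: not a substitution")
    if ndiff > 1:
        return SubstitutionClass.MULTI_HIT
    if GENETIC_CODE[a] == "*" or GENETIC_CODE[b] == "*":
        return SubstitutionClass.STOP_INVOLVING
    if GENETIC_CODE[a] == GENETIC_CODE[b]:
        return SubstitutionClass.SYNONYMOUS
    return SubstitutionClass.NONSYNONYMOUS


@lru_cache(maxsize=None)
def count_syn_nonsyn_sites(codon: str, R: float = 2.0) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for *codon* (modified
    Nei-Gojobori).

    Each position contributes one site, split between the two classes by the
    weighted fraction of its possible changes that are synonymous: a
    transition carries weight ``R/(R+2)`` and each transversion ``1/(R+2)``,
    so ``R=1`` recovers the classic unweighted counting.  Changes that would
    create a stop codon receive zero weight and the remaining weights at that
    position are renormalized (a stop-bearing variant is unobservable in a
    functional gene), which preserves ``s + a = 3`` exactly.
    """
    _check_codon(codon)
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon} has no site decomposition")
    if R < 0:
        raise ValueError("transition/transversion bias R must be >= 0")
    s = 0.0
    aa0 = GENETIC_CODE[codon]
    for pos in range(3):
        weights, syn = [], []
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            weights.append(R if is_transition(codon[pos], alt) else 1.0)
            syn.append(GENETIC_CODE[mutant] == aa0)
        total = sum(weights)
        if total > 0:
            s += sum(w for w, is_s in zip(weights, syn) if is_s) / total
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Codons differing at more than one position are resolved by averaging over
    all substitution orderings (Nei-Gojobori pathway method).  Pathways whose
    intermediate codons are stops are excluded; if every pathway is blocked,
    all pathways are used and steps into/out of a stop count as
    nonsynonymous.
    """
    a, b = _check_codon(codon_a), _check_codon(codon_b)
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool):
        sd = nd = 0.0
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != b and not allow_stops:
                return None
            if (
                GENETIC_CODE[cur] != "*"
                and GENETIC_CODE[nxt] != "*"
                and GENETIC_CODE[cur] == GENETIC_CODE[nxt]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(order, False) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, True) for order in itertools.permutations(diff_pos)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def single_nt_neighbors(codon: str) -> list[str]:
    """All nine codons one nucleotide away from *codon* (stops included)."""
    _check_codon(codon)
    out = []
    for pos in range(3):
        for alt in NUCLEOTIDES:
            if alt != codon[pos]:
                out.append(codon[:pos] + alt + codon[pos + 1 :])
    return out
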